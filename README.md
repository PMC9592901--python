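# ffforge

Force-field parameter generation for drug-like small molecules, driven by
machine-learning models over local chemical-environment descriptors.

Setting up a molecular-dynamics simulation of a small organic molecule
requires a topology: partial charges, atom types keying Lennard-Jones
parameters, and harmonic/cosine bonded constants. Producing these normally
means running quantum calculations and tools like antechamber per
molecule. `ffforge` instead describes every atom by a fixed 241-entry
numeric vector of its first, second and third bond-connectivity shells and
trains five prediction heads on those descriptors:

| head | model | output |
|---|---|---|
| charges | random forest (800 trees, depth ≤ 100) | partial charge per atom (e) |
| atom types | feed-forward net (256, 128, ReLU, Adam) | GAFF-style type code |
| torsion phase | feed-forward net | γ ∈ {0°, 180°} |
| torsion periodicity | feed-forward net | n ∈ {2, 3} |
| force constants | random forests | K_b, K_θ |

The heads are assembled into a complete GROMACS topology under the bonded
model

    V = Σ K_b (r − r0)² + Σ K_θ (θ − θ0)² + Σ K_φ [1 + cos(n φ − γ)] + nonbonded

with Lennard-Jones parameters looked up from a GAFF table by predicted
type, charges corrected so Σqᵢ equals the molecular formal charge, 1-4
pairs taken from torsion end atoms, and one planarity-preserving improper
per three-connected sp2 carbon. A Bennett-Acceptance-Ratio module builds
the 20-window Coulomb/van-der-Waals decoupling schedule and estimates
window and total solvation free energies from forward/reverse ΔU samples.

Because quantum training labels are not bundled, the package ships a fully
synthetic label suite — electronegativity-equalization (EEM) charges,
deterministic GAFF-style typing rules, and reference bonded-constant
tables — so every stage is trainable, testable, and reproducible offline.
Retraining on real ESP/DFT labels uses the same API. See
`docs/methods.md` for the science and its limits.

## Worked example

```bash
python -c "
from ffforge import synthdata, molgraph
m = synthdata.molecule_from_smiles('O=C1CCCC1', name='cyclopentanone', seed=7)
molgraph.write_structure(m, 'cyclopentanone.sdf')"
ffforge topol cyclopentanone.sdf -o cyclopentanone.itp
```

prints

```
cyclopentanone: 14 atoms, 14 bonds, 39 propers, 1 impropers, total charge -0.000000 e -> cyclopentanone.itp
```

i.e. cyclopentanone (6 heavy atoms + 8 H) gets 14 bonded atoms, 39 proper
torsions, exactly one improper (the carbonyl carbon is the only sp2
center), and charges summing to the neutral formal charge. The `[atoms]`
block of the written file starts

```
    1 o      1 MOL O1       1  -0.11394794   15.99900
    2 c      1 MOL C2       2   0.12322847   12.01100
    3 c3     1 MOL C3       3   0.12907065   12.01100
```

— the carbonyl oxygen types as `o` with a negative charge, the carbonyl
carbon as `c` with a positive one, and the ring carbons as `c3`, matching
the reference GAFF assignment (`o`, `c`, 4×`c3`, 8×`hc`). Without a
trained bundle the charges come from the EEM oracle; pass
`--bundle models.joblib` (produced by `ffforge train`) to use the ML
heads, and `--bcc corrections.csv` to apply bond charge corrections.

Library use mirrors the CLI:

```python
from ffforge import read_structure, assemble_topology, write_gromacs
mol = read_structure("cyclopentanone.sdf")
top = assemble_topology(mol)          # or assemble_topology(mol, bundle=...)
write_gromacs(top, "cyclopentanone.itp")
```

For free energies, `ffforge bar --windows dir/ --temperature 298` reads
per-window two-column (direction, ΔU) files and reports each window's BAR
ΔG ± SE plus the total solvation ΔG.

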