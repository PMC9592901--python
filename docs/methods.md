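# Methods

## Scope and model

`ffforge` generates classical force-field parameters for drug-like small
molecules (C, H, N, O, S, P, F, Cl, Br; explicit hydrogens; one connected
fragment; 3D coordinates supplied by the user) and writes them as GROMACS
topologies. The bonded energy model is the standard form

    V = Σ_bonds K_b (r − r0)²
      + Σ_angles K_θ (θ − θ0)²
      + Σ_dihedrals K_φ [1 + cos(n φ − γ)]
      + nonbonded LJ and Coulomb terms,

with no 1/2 factor on the harmonic terms internally; the GROMACS writer
emits `2·K` because GROMACS defines harmonic terms as `k/2 (x − x0)²`.
Van der Waals parameters are not re-derived: they are looked up by atom
type from a compact table of published GAFF values. Equilibrium bond
lengths **and** angles are taken from the input geometry rather than from
type-keyed tables — the bond case is the standard choice for
structure-specific topologies, and we extend it to angles for consistency,
which makes the bonded energy exactly zero at the input geometry (a useful
internal check, at the cost of baking any geometry strain into the
equilibrium values).

## Descriptors

Each atom is encoded by a frozen 241-entry vector: a 22-entry reference
block (element one-hot, Pauling electronegativity, covalent radius,
valence, hybridization one-hot, aromatic/ring/fused-ring/chiral/axial/
H-donor/H-acceptor flags), three shell-size counters, and 24 neighbor
slots (4 for the first bond shell, 8 for the second, 12 for the third) of
9 numeric features each (presence bit, atomic number, electronegativity,
bond order and bond length to the parent shell, aromaticity, hybridization
code, ring and fused-ring flags). Absent neighbors stay at the padding
value 0 with presence 0; slots within a shell are sorted by their full
feature tuple so the vector is invariant to input atom ordering; when a
shell overflows its slots the canonically-first neighbors are kept and the
shell-size counter records the true occupancy. Torsion descriptors
concatenate the four atom blocks (in index-canonical direction, so a
quadruple and its reversal featurize identically) plus the signed dihedral
value; bond and angle descriptors concatenate two or three atom blocks
(symmetry-sorted) plus order/length or the angle value.

The slot layout (4/8/12 × 9 entries) is a design choice: the descriptor
ingredients and the total width are fixed requirements, but no published
enumeration of the individual entries exists, so any layout carrying those
ingredients at that width is equally valid. The manifest is versioned and
frozen per trained model.

## Chemical perception and atom typing

Perception (aromaticity, hybridization, rings, stereo flags) is delegated
to RDKit's ring-based aromaticity model on a sanitized rebuild of the
graph, and pinned by fixture tests. The H-bond rule is deliberately
simple: donors are N/O/S bearing a hydrogen, acceptors are any O plus any
N that is not a three-connected aromatic (pyrrole-type) nitrogen. The
"axial" flag is retained in the vocabulary but always False — a reliable
ring-axis assignment needs conformational analysis that is out of scope —
so it contributes a constant column.

Atom typing is a deterministic first-match-wins rule cascade over the
perceived environment, emitting GAFF-style codes (c3/ca/c/hc/ha/hn/nh/o/
oh/os/...). The conjugation-direction pairs (cc/cd, ce/cf, cg/ch, nc/nd,
ne/nf) are resolved by a fixed index-parity convention; within GAFF each
pair shares van der Waals parameters, so either member keys identical
nonbonded parameters and classifier confusions inside a pair are
parameter-neutral. Electron-withdrawal-dependent hydrogen types count
N/O/S/F/Cl/Br neighbors on the parent carbon. The cascade is total over
the supported vocabulary and raises a typed error naming the atom
otherwise.

## Synthetic labels

Training the heads requires per-atom reference labels; quantum ESP charges
are replaced by a closed-form surrogate so the whole pipeline is trainable
and testable offline:

* **Charges** — electronegativity equalization (EEM): minimize
  Σ (χᵢqᵢ + ½ηᵢqᵢ²) + Σ Jᵢⱼqᵢqⱼ subject to Σq = Q, a single linear
  (KKT) solve. Per-element χ/η are Pearson's absolute electronegativity
  and hardness (eV, eV/e); the coupling is damped Coulomb
  J = 14.4 eV·Å / √(r² + d²) with d = 1.8 Å, which keeps the interaction
  finite at bonded distances while preserving the geometry dependence the
  shell descriptors must capture. EEM charges are *not* ESP/DFT charges;
  recovery scores measure how well the models learn the surrogate oracle,
  not quantum accuracy.
* **Atom types** — the rule cascade above.
* **Torsion phase/periodicity** — a central-bond character table:
  aromatic or double central bonds are planarity-preserving (γ = 180°,
  n = 2, stiff K_φ), conjugated single bonds likewise with intermediate
  K_φ, saturated rotors threefold (γ = 0°, n = 3, soft K_φ).
* **Bond/angle force constants** — element-pair/bond-class and
  apex-element reference tables with representative GAFF magnitudes,
  modulated by hydrogen flanks and aromaticity so the label is a
  deterministic, descriptor-visible function of the environment.

Fixture molecules come from a curated catalog plus a combinatorial
substituted-scaffold pool (chains, benzenes, cyclohexanes, pyridines ×
alcohol/thiol/amide/amine/aldehyde/ketone/nitro/nitrile/ester/halogen
substituents, ~560 distinct species), embedded with RDKit's
distance-geometry method under fixed per-molecule seeds and refined with
MMFF94. Embedded geometries were preferred over hand-built idealized
templates because they are equally deterministic given the seed and give
chemically sensible ring geometries without maintaining template tables.
The generator does **not** emulate: conformational diversity (one
conformer per molecule), protonation equilibria, CHEMBL-scale chemical
space, or any correlation structure of real quantum charge sets — so
passing recovery tests demonstrates that the descriptor/model machinery
can learn a local-environment labeling at this scale, not that it
reproduces DFT-quality charges.

## Models

* Charge head: random forest, 800 trees, max depth 100, MSE criterion.
* Classifier heads (atom type, phase, periodicity): standardized inputs →
  two hidden layers (256, 128), ReLU, Adam, learning rate 0.001, log-loss,
  max 400 iterations. The hidden sizes are our choice (pinned in config):
  large enough to separate ~40 type classes, small enough to train in
  seconds at this data scale.
* Force constants: random forests (200 trees) on bond/angle descriptors;
  predictions are clipped positive (labels are positive, so the clip is a
  guard, not a correction).
* Protocol: 80/20 split stratified **by molecule** (never by row, to
  avoid twin-atom leakage), 5-fold grouped cross-validation on the
  training portion, per-class precision/recall/F1 on the holdout. All
  fits are deterministic given the seed.
* Dihedral stiffness K_φ is taken from the reference table keyed by
  central-bond character; the ML heads supply only γ and n. This is the
  minimal-assumption division of labor given that no trained source for
  K_φ is available.

At the default study scale (500 molecules, ≈7,800 atoms, ≈15,000
torsions) the full train-and-validate run completes in minutes on one
CPU; the trained charge head recovers held-out EEM labels with R² ≥ 0.95
and the type head recovers the rule oracle with accuracy ≥ 0.95.

## Topology assembly

Raw predicted charges rarely sum to the molecular formal charge; the
residual (Q − Σq)/N is added to every atom, making the sum exact. Optional
bond charge corrections are antisymmetric per-bond increments keyed by
directed type pattern and bond order; two rules matching one bond is an
error, and the total charge is invariant by construction. The shipped BCC
table is empty — increments are system-specific and user-supplied.
1-4 pairs are the end atoms of proper torsions at graph distance exactly
three (ring short-circuits excluded); impropers are one per
three-connected sp2 carbon with the central atom third, γ = 180°, n = 2,
K = 10.5 kcal/mol at carbonyl centers and 1.1 kcal/mol otherwise.

The writer emits AMBER-convention GROMACS files: nbfunc 1, combination
rule 2, fudgeLJ 0.5, fudgeQQ 0.8333, bonds/angles/pairs func 1, proper
dihedrals func 9, impropers func 4, σ in nm, energies in kJ/mol, harmonic
constants doubled as described above. A validating reader parses files
back to internal units; write→read→write is a textual fixed point, and
round-trip values agree to 1e-6.

## Free energy machinery

The decoupling schedule is Coulomb first (λ = 0 → 1, step 0.25, vdW
untouched), then van der Waals with the non-uniform ladder (0.05 … 1.0,
denser above 0.6), 20 windows total. Window ΔG values use the Bennett
Acceptance Ratio: the self-consistent balance of forward and reverse
Fermi-weighted energy differences, generalized with the ln(n_F/n_R)
offset for unequal sample counts (it reduces to the equal-count balance
when n_F = n_R). The left and right sides are strictly monotone in ΔG, so
the root is unique whenever the work distributions overlap; it is found
by bracketed root-finding (bracket seeded by the two one-sided
exponential-averaging estimates, expanded until a sign change) to 1e-8
kcal/mol. If the balance underflows to 0 = 0 — non-overlapping
distributions — the estimator raises "insufficient overlap" rather than
returning an endpoint. Uncertainty is the Bennett asymptotic variance of
the Fermi weights at the solution; this choice (rather than, say, block
bootstrap) assumes uncorrelated samples. Temperature defaults to 298 K
with β in mol/kcal. The total solvation free energy is minus the sum of
window ΔG values (decoupling sign convention) with errors combined in
quadrature. Generating ΔU samples is an MD engine's job and out of scope;
window files are plain two-column text.

BAR is validated two independent ways: against the analytic Gaussian
fluctuation-relation identity (forward work N(μ, σ²) ⇒ ΔG = μ − βσ²/2)
and against a separately coded Bennett fixed-point iteration, agreeing to
1e-6 kcal/mol on shared samples.

## Numerical choices and degenerate inputs

* Dihedral angles are signed, in (−180°, 180°], via the atan2
  construction; bond lengths are stored and re-derivable from coordinates
  to 1e-6 Å.
* Multi-fragment inputs, 2D coordinates, and out-of-vocabulary elements
  are rejected with specific messages rather than repaired.
* Shell depth is limited to 3 by the descriptor contract.
* The EEM solve raises on singular KKT systems ("degenerate EEM
  parameters"); η ≤ 0 is rejected at construction.
* Classifier heads refuse single-class datasets ("degenerate labels");
  regression heads refuse datasets smaller than the fold count.

## Known limitations

* Charges are only as good as their training labels; the shipped surrogate
  is EEM, so absolute charge values are not ESP-quality. Retraining on
  user-supplied quantum labels uses the same API.
* The type cascade covers common organic chemistry; exotic valences
  (hypervalent halogens, boron, metals) are rejected, and cq is reachable
  only through the bridge-parity rule.
* One improper per sp2 carbon only — sp2 nitrogens are not restrained,
  matching the carbon-centered enumeration rule.
* The LJ/bonded reference tables are compact representative sets, not the
  full GAFF parameter file; unusual type pairs fall back to graded
  element-pair defaults.
* `axial` is a constant column until a ring-axis perception is added.
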