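"""Synthetic training data: fixture molecules and surrogate labels.

Training the charge / atom-type / torsion heads needs per-atom reference
labels.  The quantum-derived ESP charges such models are normally fit to
require electronic-structure calculations, so this module supplies a fully
synthetic, closed-form label source instead:

* **Charges** come from the electronegativity equalization method (EEM):
  minimize  E(q) = sum_i (chi_i q_i + 1/2 eta_i q_i^2)
                   + sum_{i<j} J_ij q_i q_j   subject to  sum_i q_i = Q,
  a linear solve whose solution has the neighborhood dependence a shell
  descriptor must capture.  EEM charges are *not* ESP/DFT charges; they are
  a self-consistent surrogate oracle, nothing more.
* **Atom types** come from the deterministic rule cascade in
  :mod:`ffforge.atomtype_rules`.
* **Torsion phase/periodicity and force constants** come from the
  GAFF-style reference table in :mod:`ffforge.gaffdata`.

Fixture molecules are built from a curated SMILES catalog spanning
alcohols, thiols, amides, amines, aldehydes, ketones, nitro, nitrile,
ether/ester, aromatic and halogenated chemistry, embedded in 3D with
RDKit's distance-geometry embedding (fixed per-molecule seeds) followed by
MMFF94 refinement, so geometries are deterministic and chemically sensible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit import RDLogger

from . import atomtype_rules, gaffdata
from .descriptors import TrainingDataset, build_dataset
from .molgraph import Molecule, MoleculeError, from_rdkit, internal_coordinates

RDLogger.DisableLog("rdApp.*")

# --------------------------------------------------------------------------
# EEM surrogate charges
# --------------------------------------------------------------------------

#: Mulliken-scale electronegativity chi (eV) and hardness eta (eV/e),
#: Pearson's absolute values.
DEFAULT_EEM = {
    "H": (7.18, 12.90), "C": (6.27, 10.00), "N": (7.30, 14.46),
    "O": (7.54, 12.16), "F": (10.41, 14.02), "S": (6.22, 8.28),
    "P": (5.62, 9.76), "Cl": (8.30, 9.36), "Br": (7.59, 8.44),
}

#: Coulomb prefactor e^2/(4 pi eps0), eV * Angstrom.
_COULOMB_EV_A = 14.399645

#: Damping length (Angstrom) in J_ij = k / sqrt(r^2 + d^2); keeps the
#: coupling finite at bonded distances.
_DAMPING_A = 1.8


@dataclass(frozen=True)
class EEMParameters:
    """Per-element (chi, eta) with optional damped-Coulomb coupling."""

    table: dict = field(default_factory=lambda: dict(DEFAULT_EEM))
    coulomb: float = _COULOMB_EV_A
    damping: float = _DAMPING_A

    def __post_init__(self):
        for el, (_, eta) in self.table.items():
            if eta <= 0:
                raise ValueError(f"degenerate EEM parameters: eta <= 0 for {el}")


DEFAULT_EEM_PARAMS = EEMParameters()


def eem_charges(mol: Molecule,
                params: EEMParameters = DEFAULT_EEM_PARAMS) -> np.ndarray:
    """Closed-form EEM charges (e) with sum constrained to the formal charge.

    Solves the (n+1)x(n+1) KKT system of the quadratic energy model; raises
    "degenerate EEM parameters" if the system is singular.
    """
    n = mol.n_atoms
    chi = np.empty(n)
    eta = np.empty(n)
    for i, a in enumerate(mol.atoms):
        if a.element not in params.table:
            raise MoleculeError(f"element out of vocabulary: {a.element}")
        chi[i], eta[i] = params.table[a.element]

    A = np.zeros((n + 1, n + 1))
    A[np.arange(n), np.arange(n)] = eta
    if params.coulomb and n > 1:
        d = mol.coordinates[:, None, :] - mol.coordinates[None, :, :]
        r2 = np.sum(d * d, axis=-1)
        J = params.coulomb / np.sqrt(r2 + params.damping ** 2)
        np.fill_diagonal(J, 0.0)
        A[:n, :n] += J
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    rhs = np.concatenate([-chi, [float(mol.formal_charge)]])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate EEM parameters") from exc
    return sol[:n]


# --------------------------------------------------------------------------
# Fixture molecules
# --------------------------------------------------------------------------

#: Named reference molecules (functional-group anchors).
NAMED_SMILES = {
    "methane": "C",
    "ethane": "CC",
    "butane": "CCCC",
    "benzene": "c1ccccc1",
    "cyclopentanone": "O=C1CCCC1",
    "aniline": "Nc1ccccc1",
    "1-octanol": "CCCCCCCCO",
}

#: Curated variety set: one functional group per line, small and embeddable.
CATALOG_SMILES = [
    "CO", "CCO", "CC(C)O", "OCC(O)CO",                      # alcohols
    "CS", "CCS", "CSSC", "CSC",                             # thiols/sulfides
    "CC(N)=O", "CNC(C)=O", "NC=O",                          # amides
    "CN", "CCN", "CN(C)C", "NCCN", "C[NH3+]",               # amines
    "CC=O", "CCC=O", "O=Cc1ccccc1",                         # aldehydes
    "CC(C)=O", "CCC(C)=O", "O=C1CCCCC1",                    # ketones
    "C[N+](=O)[O-]", "O=[N+]([O-])c1ccccc1",                # nitro
    "CC#N", "N#Cc1ccccc1",                                  # nitriles
    "CC(=O)O", "OC(=O)c1ccccc1", "CC(=O)OC",                # acids/esters
    "COC", "CCOC", "C1CCOC1", "c1ccoc1",                    # ethers/furan
    "CF", "CCl", "CBr", "FC(F)F", "Clc1ccccc1",             # halogens
    "C=C", "CC=C", "C=CC=C", "C#C", "CC#C",                 # alkenes/alkynes
    "c1ccncc1", "c1cc[nH]c1", "c1ccsc1", "Cc1ccccc1",       # heteroaromatics
    "c1ccc2ccccc2c1", "c1ccc(-c2ccccc2)cc1",                # fused/biphenyl
    "C1CC1", "C1CCC1", "C1CCCC1", "C1CCCCC1",               # carbocycles
    "CC(C)(C)O", "CC(C)C", "CCCCCC",                        # branched/chains
    "OCc1ccccc1", "Nc1ccc(O)cc1", "CSc1ccccc1",             # aryl subst.
    "CP(C)C", "CO[P](=O)(OC)OC", "CS(C)=O", "CS(C)(=O)=O",  # P/S oxo
]

#: Substituent fragments for combinatorial library generation.
_SUBSTITUENTS = ["O", "N", "S", "C", "CC", "C#N", "C=O", "C(C)=O", "C(N)=O",
                 "C(=O)O", "C(=O)OC", "OC", "[N+](=O)[O-]", "F", "Cl", "Br"]
_CHAINS = ["C", "CC", "CCC", "CCCC", "CCCCC", "CC(C)C", "CCC(C)C"]


def _enumerate_library_smiles() -> list[str]:
    """Deterministic combinatorial SMILES pool (~700 valid molecules)."""
    pool = []
    for chain in _CHAINS:
        for sub in _SUBSTITUENTS:
            pool.append(chain + sub)
    for sub in _SUBSTITUENTS:
        pool.append(f"c1ccc({sub})cc1")
        pool.append(f"C1CCC({sub})CC1")
        pool.append(f"c1ccc({sub})nc1")
    for a in _SUBSTITUENTS:
        for b in _SUBSTITUENTS:
            pool.append(f"c1cc({a})ccc1{b}")
            pool.append(f"c1c({a})cccc1{b}")
            pool.append(f"C1CC({a})CCC1{b}")
    seen, out = set(), []
    for smi in pool:
        m = Chem.MolFromSmiles(smi)
        if m is None:
            continue
        can = Chem.MolToSmiles(m)
        if can not in seen:
            seen.add(can)
            out.append(can)
    return out


def molecule_from_smiles(smiles: str, name: str = "",
                         seed: int = 2025) -> Molecule:
    """SMILES -> explicit-H 3D Molecule (seeded ETKDG + MMFF94 refinement)."""
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise MoleculeError(f"bad SMILES: {smiles}")
    rdmol = Chem.AddHs(rdmol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31 - 1)
    if AllChem.EmbedMolecule(rdmol, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(rdmol, params) != 0:
            raise MoleculeError(f"embedding failed: {smiles}")
    try:
        AllChem.MMFFOptimizeMolecule(rdmol, maxIters=500)
    except Exception:
        pass  # unrefined DG geometry is still usable
    return from_rdkit(rdmol, name=name or smiles)


@dataclass
class FixtureSet:
    """Named fixture molecules plus a functional-group coverage report."""

    molecules: dict[str, Molecule]

    def __iter__(self):
        return iter(self.molecules.values())

    def __len__(self):
        return len(self.molecules)

    def __getitem__(self, name: str) -> Molecule:
        return self.molecules[name]

    def coverage_report(self) -> dict[str, int]:
        """Counts of functional-group-indicative atom types present."""
        counts: dict[str, int] = {}
        for mol in self:
            for code in atomtype_rules.assign_atom_types(mol):
                counts[code] = counts.get(code, 0) + 1
        return counts


def fixture_molecules(seed: int = 7, n_generated: int = 50) -> FixtureSet:
    """The named anchor molecules plus ``n_generated`` catalog molecules.

    Deterministic for a given seed: the catalog order is fixed and the
    per-molecule embedding seed is derived from ``seed``.
    """
    mols: dict[str, Molecule] = {}
    for name, smi in NAMED_SMILES.items():
        mols[name] = molecule_from_smiles(smi, name=name, seed=seed)
    pool = CATALOG_SMILES + [s for s in _enumerate_library_smiles()
                             if s not in CATALOG_SMILES]
    count = 0
    for k, smi in enumerate(pool):
        if count >= n_generated:
            break
        try:
            mol = molecule_from_smiles(smi, name=f"gen_{k}", seed=seed + k + 1)
        except MoleculeError:
            continue
        mols[mol.name] = mol
        count += 1
    return FixtureSet(molecules=mols)


# --------------------------------------------------------------------------
# Label sources and training-set bundle
# --------------------------------------------------------------------------

def torsion_labels(mol: Molecule) -> list[tuple[float, int]]:
    """(phase_deg, periodicity) per proper torsion, GAFF-convention table."""
    types = atomtype_rules.assign_atom_types(mol)
    out = []
    for t in internal_coordinates(mol).torsions:
        a, b, c, d = t[:4]
        _, n, gamma = gaffdata.torsion_reference(mol, b, c)
        out.append((gamma, n))
    return out


@dataclass
class TrainingBundle:
    """All five aligned datasets produced from one fixture set."""

    charges: TrainingDataset
    atom_types: TrainingDataset
    phase: TrainingDataset
    periodicity: TrainingDataset
    bond_k: TrainingDataset
    angle_k: TrainingDataset


def make_training_set(fixtures: FixtureSet,
                      params: EEMParameters = DEFAULT_EEM_PARAMS
                      ) -> TrainingBundle:
    """Featurize every fixture and attach the full synthetic label suite."""
    mols = list(fixtures)

    def charge_labels(mol):
        return eem_charges(mol, params)

    def type_labels(mol):
        return atomtype_rules.assign_atom_types(mol)

    def phase_labels(mol):
        return [g for g, n in torsion_labels(mol)]

    def per_labels(mol):
        return [n for g, n in torsion_labels(mol)]

    def bond_labels(mol):
        return [gaffdata.bond_force_constant(mol, b.i, b.j) for b in mol.bonds]

    def angle_labels(mol):
        ic = internal_coordinates(mol)
        return [gaffdata.angle_force_constant(mol, i, j, k)
                for i, j, k, _ in ic.angles]

    return TrainingBundle(
        charges=build_dataset(mols, charge_labels, kind="atom"),
        atom_types=build_dataset(mols, type_labels, kind="atom"),
        phase=build_dataset(mols, phase_labels, kind="torsion"),
        periodicity=build_dataset(mols, per_labels, kind="torsion"),
        bond_k=build_dataset(mols, bond_labels, kind="bond"),
        angle_k=build_dataset(mols, angle_labels, kind="angle"),
    )
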