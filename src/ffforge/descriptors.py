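"""Fixed-width numeric descriptors of atomic chemical environments.

Every atom is encoded as a 241-entry vector describing the reference atom
and its first, second and third bond-connectivity shells:

* reference block (22): element one-hot (9), electronegativity, covalent
  radius, valence, hybridization one-hot (sp/sp2/sp3), and the aromatic /
  ring / fused-ring / chiral / axial / H-donor / H-acceptor flags;
* shell sizes (3): the true number of atoms in shells 1-3 (this also
  signals overflow when a shell holds more atoms than it has slots);
* 24 neighbor slots (4 for shell 1, 8 for shell 2, 12 for shell 3), 9
  entries each: presence bit, atomic number, electronegativity, bond order
  to the parent shell (1.5 for aromatic), bond length to parent (Angstrom),
  aromatic flag, hybridization code (sp=1, sp2=2, sp3=3, other=0), ring
  flag, fused-ring flag.

Absent neighbors stay at the padding value 0 with presence bit 0.  Slots
within a shell are ordered by their full feature tuple (descending), so the
vector is invariant to input atom reordering.  Torsion, bond and angle
descriptors are concatenations of atom vectors plus the geometric value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .molgraph import (ATOMIC_NUMBER, SUPPORTED_ELEMENTS, InternalCoordinates,
                       Molecule, MoleculeError, internal_coordinates,
                       shell_atoms)

ATOM_VECTOR_WIDTH = 241
SHELL_SLOTS = (4, 8, 12)
SLOT_WIDTH = 9
PADDING_VALUE = 0.0

_HYB_CODE = {"sp": 1.0, "sp2": 2.0, "sp3": 3.0, "other": 0.0}


@dataclass(frozen=True)
class DescriptorManifest:
    """Versioned, frozen description of the atom-vector layout."""

    version: str = "1"
    width: int = ATOM_VECTOR_WIDTH
    shell_slots: tuple[int, ...] = SHELL_SLOTS
    slot_width: int = SLOT_WIDTH
    padding_value: float = PADDING_VALUE
    feature_names: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.feature_names:
            object.__setattr__(self, "feature_names",
                               tuple(_default_feature_names(self)))
        if self.width != ATOM_VECTOR_WIDTH or len(self.feature_names) != self.width:
            raise ValueError("manifest mismatch")


def _default_feature_names(m: DescriptorManifest) -> list[str]:
    names = [f"ref_elem_{e}" for e in SUPPORTED_ELEMENTS]
    names += ["ref_en", "ref_radius", "ref_valence",
              "ref_hyb_sp", "ref_hyb_sp2", "ref_hyb_sp3",
              "ref_aromatic", "ref_ring", "ref_fused", "ref_chiral",
              "ref_axial", "ref_donor", "ref_acceptor"]
    names += [f"shell{k}_size" for k in (1, 2, 3)]
    slot_feats = ["present", "z", "en", "order", "length",
                  "aromatic", "hyb", "ring", "fused"]
    for k, nslots in zip((1, 2, 3), m.shell_slots):
        for s in range(nslots):
            names += [f"s{k}_{s}_{f}" for f in slot_feats]
    return names


DEFAULT_MANIFEST = DescriptorManifest()


@dataclass
class AtomFeatureVector:
    values: np.ndarray
    manifest_version: str = DEFAULT_MANIFEST.version

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (ATOM_VECTOR_WIDTH,):
            raise ValueError("manifest mismatch")


@dataclass
class TorsionFeatureVector:
    values: np.ndarray
    dihedral_value: float


# --------------------------------------------------------------------------
# Atom featurization
# --------------------------------------------------------------------------

def _reference_block(mol: Molecule, idx: int) -> list[float]:
    a = mol.atoms[idx]
    vec = [1.0 if a.element == e else 0.0 for e in SUPPORTED_ELEMENTS]
    vec += [a.electronegativity, a.covalent_radius, float(a.valence)]
    vec += [1.0 if a.hybridization == h else 0.0 for h in ("sp", "sp2", "sp3")]
    vec += [float(a.aromatic), float(a.in_ring), float(a.in_fused_ring),
            float(a.chiral), float(a.axial), float(a.h_donor),
            float(a.h_acceptor)]
    return vec


def _slot_tuple(mol: Molecule, member: int, parents: set[int]) -> tuple:
    """Feature tuple for one shell member relative to its parent shell."""
    a = mol.atoms[member]
    best_order, best_len = 0.0, 0.0
    for p in parents:
        b = mol.bond_between(member, p)
        if b is None:
            continue
        order = 1.5 if b.aromatic else float(b.order_kekule)
        if order > best_order or (order == best_order and
                                  (best_len == 0.0 or b.length < best_len)):
            best_order, best_len = order, b.length
    return (1.0, float(ATOMIC_NUMBER[a.element]), a.electronegativity,
            best_order, best_len, float(a.aromatic), _HYB_CODE[a.hybridization],
            float(a.in_ring), float(a.in_fused_ring))


def featurize_atom(mol: Molecule, atom_index: int,
                   manifest: DescriptorManifest = DEFAULT_MANIFEST
                   ) -> AtomFeatureVector:
    """Encode one atom's 3-shell environment as a 241-entry vector."""
    if manifest.width != ATOM_VECTOR_WIDTH:
        raise ValueError("manifest mismatch")
    if not mol.perceived:
        raise MoleculeError("molecule not perceived")
    vec = _reference_block(mol, atom_index)

    shells = [shell_atoms(mol, atom_index, k) for k in (1, 2, 3)]
    vec += [float(len(s)) for s in shells]

    prev = {atom_index}
    for shell, nslots in zip(shells, manifest.shell_slots):
        tuples = sorted((_slot_tuple(mol, m, prev) for m in shell),
                        reverse=True)
        tuples = tuples[:nslots]  # canonical-first kept on overflow
        for t in tuples:
            vec += list(t)
        for _ in range(nslots - len(tuples)):
            vec += [manifest.padding_value] * manifest.slot_width
        prev = shell
    return AtomFeatureVector(np.array(vec), manifest.version)


def featurize_molecule(mol: Molecule,
                       manifest: DescriptorManifest = DEFAULT_MANIFEST
                       ) -> np.ndarray:
    """(n_atoms, 241) feature matrix for a whole molecule."""
    return np.vstack([featurize_atom(mol, i, manifest).values
                      for i in range(mol.n_atoms)])


# --------------------------------------------------------------------------
# Torsion / bond / angle featurization
# --------------------------------------------------------------------------

def _check_torsion(mol: Molecule, quad: Sequence[int]) -> None:
    a, b, c, d = quad
    ok = (len({a, b, c, d}) == 4
          and mol.bond_between(a, b) is not None
          and mol.bond_between(b, c) is not None
          and mol.bond_between(c, d) is not None)
    if not ok:
        raise MoleculeError(f"not a torsion: {tuple(quad)}")


def canonical_torsion(quad: Sequence[int]) -> tuple[int, int, int, int]:
    q = tuple(int(x) for x in quad)
    return min(q, q[::-1])


def featurize_torsion(mol: Molecule, quad: Sequence[int],
                      manifest: DescriptorManifest = DEFAULT_MANIFEST
                      ) -> TorsionFeatureVector:
    """Concatenated atom blocks of a proper torsion plus its dihedral value.

    The quadruple is canonicalized so (a,b,c,d) and (d,c,b,a) featurize
    identically.  Width: 4 x 241 + 1 = 965.
    """
    _check_torsion(mol, quad)
    from .molgraph import dihedral_deg
    a, b, c, d = canonical_torsion(quad)
    phi = dihedral_deg(mol.coordinates, a, b, c, d)
    blocks = [featurize_atom(mol, i, manifest).values for i in (a, b, c, d)]
    values = np.concatenate(blocks + [np.array([phi])])
    return TorsionFeatureVector(values=values, dihedral_value=phi)


def featurize_bond(mol: Molecule, pair: Sequence[int],
                   manifest: DescriptorManifest = DEFAULT_MANIFEST) -> np.ndarray:
    """Symmetric bond descriptor: two atom blocks + [order, length]."""
    i, j = int(pair[0]), int(pair[1])
    b = mol.bond_between(i, j)
    if b is None:
        raise MoleculeError(f"not a bond: ({i}, {j})")
    vi = featurize_atom(mol, i, manifest).values
    vj = featurize_atom(mol, j, manifest).values
    first, second = sorted([vi, vj], key=lambda v: tuple(v), reverse=True)
    order = 1.5 if b.aromatic else float(b.order_kekule)
    return np.concatenate([first, second, [order, b.length]])


def featurize_angle(mol: Molecule, triple: Sequence[int],
                    manifest: DescriptorManifest = DEFAULT_MANIFEST) -> np.ndarray:
    """Symmetric angle descriptor: three atom blocks + [theta_deg]."""
    from .molgraph import angle_deg
    i, j, k = (int(x) for x in triple)
    if mol.bond_between(i, j) is None or mol.bond_between(j, k) is None:
        raise MoleculeError(f"not an angle: ({i}, {j}, {k})")
    vi = featurize_atom(mol, i, manifest).values
    vj = featurize_atom(mol, j, manifest).values
    vk = featurize_atom(mol, k, manifest).values
    first, last = sorted([vi, vk], key=lambda v: tuple(v), reverse=True)
    theta = angle_deg(mol.coordinates, i, j, k)
    return np.concatenate([first, vj, last, [theta]])


# --------------------------------------------------------------------------
# Dataset assembly
# --------------------------------------------------------------------------

@dataclass
class TrainingDataset:
    """Aligned feature matrix / label vector with row provenance."""

    X: np.ndarray
    y: np.ndarray
    provenance: list[tuple[str, tuple]]
    kind: str = "atom"

    @property
    def n_rows(self) -> int:
        return 0 if self.X.size == 0 else self.X.shape[0]

    def molecule_names(self) -> list[str]:
        return [p[0] for p in self.provenance]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X)
        df.insert(0, "molecule", [p[0] for p in self.provenance])
        df.insert(1, "item", [str(p[1]) for p in self.provenance])
        df["label"] = self.y
        return df

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


LabelSource = Callable[[Molecule], Sequence]


def build_dataset(mols: Sequence[Molecule], labels: LabelSource,
                  kind: str = "atom",
                  manifest: DescriptorManifest = DEFAULT_MANIFEST
                  ) -> TrainingDataset:
    """Featurize all atoms (or torsions/bonds/angles) with aligned labels.

    ``labels(mol)`` must return one label per item of the requested kind;
    a length mismatch or a None label raises "incomplete labels".
    """
    rows, ys, prov = [], [], []
    for mol in mols:
        if kind == "atom":
            items = [(i,) for i in range(mol.n_atoms)]
            feats = [featurize_atom(mol, i, manifest).values
                     for i in range(mol.n_atoms)]
        elif kind == "torsion":
            ic = internal_coordinates(mol)
            items = [t[:4] for t in ic.torsions]
            feats = [featurize_torsion(mol, it, manifest).values for it in items]
        elif kind == "bond":
            items = [(b.as_tuple()) for b in mol.bonds]
            feats = [featurize_bond(mol, it, manifest) for it in items]
        elif kind == "angle":
            ic = internal_coordinates(mol)
            items = [a[:3] for a in ic.angles]
            feats = [featurize_angle(mol, it, manifest) for it in items]
        else:
            raise ValueError(f"unknown dataset kind: {kind}")
        lab = list(labels(mol))
        if len(lab) != len(items) or any(l is None for l in lab):
            raise ValueError(f"incomplete labels for molecule {mol.name!r}")
        rows.extend(feats)
        ys.extend(lab)
        prov.extend((mol.name, tuple(it)) for it in items)
    X = np.vstack(rows) if rows else np.empty((0, manifest.width))
    return TrainingDataset(X=X, y=np.asarray(ys), provenance=prov, kind=kind)
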