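"""Molecular graphs, chemical perception, and internal coordinates.

This module is the front door of the pipeline: it reads a small-molecule
structure (SDF or MOL2, explicit hydrogens, 3D coordinates), builds a typed
molecular graph, perceives aromaticity / hybridization / ring membership /
hydrogen-bonding roles, and enumerates the internal coordinates (bonds,
angles, proper torsions) that the bonded terms of a classical force field

    V = sum_bonds K_b (r - r0)^2 + sum_angles K_theta (theta - theta0)^2
        + sum_dihedrals K_phi [1 + cos(n phi - gamma)] + nonbonded terms

are built from.  Distances are Angstrom and angles degrees throughout; unit
conversion happens only in the GROMACS writer.

Chemical perception is delegated to RDKit (ring-based aromaticity model,
hybridization from valence); the graph type itself is toolkit-agnostic so
the rest of the package never touches an RDKit object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit.Chem import rdmolops

# --------------------------------------------------------------------------
# Element vocabulary
# --------------------------------------------------------------------------

#: Supported elements (organic subset + halogens).
SUPPORTED_ELEMENTS = ("C", "H", "O", "N", "S", "P", "F", "Cl", "Br")

#: Pauling electronegativities (dimensionless).
ELECTRONEGATIVITY = {
    "H": 2.20, "C": 2.55, "N": 3.04, "O": 3.44, "S": 2.58,
    "P": 2.19, "F": 3.98, "Cl": 3.16, "Br": 2.96,
}

#: Single-bond covalent radii, Angstrom.
COVALENT_RADIUS = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05,
    "P": 1.07, "F": 0.57, "Cl": 1.02, "Br": 1.20,
}

#: Standard atomic masses, u.
ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "Cl": 35.45, "Br": 79.904,
}

ATOMIC_NUMBER = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9,
    "P": 15, "S": 16, "Cl": 17, "Br": 35,
}


class MoleculeError(ValueError):
    """Raised for structurally invalid or unsupported input molecules."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class Atom:
    """One atom of the molecular graph with its perceived environment.

    ``hybridization`` is one of ``sp``, ``sp2``, ``sp3``, ``other``; the
    boolean flags are filled by :func:`perceive_environment`. ``axial`` is
    retained in the descriptor vocabulary but set False unless a stereocenter
    ring-axis assignment is possible (it rarely is without full 3D stereo
    analysis), so it defaults to False.
    """

    index: int
    element: str
    electronegativity: float = 0.0
    covalent_radius: float = 0.0
    valence: int = 0
    hybridization: str = "other"
    aromatic: bool = False
    in_ring: bool = False
    in_fused_ring: bool = False
    h_donor: bool = False
    h_acceptor: bool = False
    chiral: bool = False
    axial: bool = False
    formal_charge: int = 0  # per-atom input charge, needed for valence models


@dataclass
class Bond:
    """Edge of the graph. ``order`` is 1/2/3 or ``"aromatic"``.

    ``order_kekule`` always holds an integer Kekule order so bonded-parameter
    lookups never see the symbolic aromatic order.
    """

    i: int
    j: int
    order: object
    length: float
    order_kekule: int = 1
    aromatic: bool = False

    def as_tuple(self) -> tuple[int, int]:
        return (self.i, self.j) if self.i < self.j else (self.j, self.i)


@dataclass
class Molecule:
    """Connected molecular graph with 3D coordinates (Angstrom)."""

    atoms: list[Atom]
    bonds: list[Bond]
    coordinates: np.ndarray
    formal_charge: int = 0
    name: str = ""
    perceived: bool = False

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def graph(self) -> nx.Graph:
        """Connectivity as a networkx graph (nodes = atom indices)."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from((b.i, b.j) for b in self.bonds)
        return g

    def neighbors(self, idx: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == idx:
                out.append(b.j)
            elif b.j == idx:
                out.append(b.i)
        return sorted(out)

    def bond_between(self, i: int, j: int) -> Bond | None:
        key = (i, j) if i < j else (j, i)
        for b in self.bonds:
            if b.as_tuple() == key:
                return b
        return None

    def validate(self) -> None:
        n = self.n_atoms
        if n == 0:
            raise MoleculeError("empty molecule")
        if self.coordinates.shape != (n, 3):
            raise MoleculeError("no 3D coordinates")
        for b in self.bonds:
            if b.i == b.j or not (0 <= b.i < n and 0 <= b.j < n):
                raise MoleculeError(f"invalid bond {b.i}-{b.j}")
        for a in self.atoms:
            if a.element not in SUPPORTED_ELEMENTS:
                raise MoleculeError(f"element out of vocabulary: {a.element}")
        if n > 1 and not nx.is_connected(self.graph()):
            raise MoleculeError("multi-fragment input")


@dataclass
class InternalCoordinates:
    """Exhaustive, duplicate-free bonded-term enumeration.

    bonds:    [(i, j, r)]          r in Angstrom
    angles:   [(i, j, k, theta)]   theta in degrees, j is the apex
    torsions: [(a, b, c, d, phi)]  phi in degrees in (-180, 180]
    """

    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    angles: list[tuple[int, int, int, float]] = field(default_factory=list)
    torsions: list[tuple[int, int, int, int, float]] = field(default_factory=list)


# --------------------------------------------------------------------------
# Geometry helpers
# --------------------------------------------------------------------------

def distance(coords: np.ndarray, i: int, j: int) -> float:
    return float(np.linalg.norm(coords[i] - coords[j]))


def angle_deg(coords: np.ndarray, i: int, j: int, k: int) -> float:
    """Angle i-j-k in degrees."""
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def dihedral_deg(coords: np.ndarray, a: int, b: int, c: int, d: int) -> float:
    """Signed dihedral a-b-c-d in degrees, in (-180, 180]."""
    b0 = coords[a] - coords[b]
    b1 = coords[c] - coords[b]
    b2 = coords[d] - coords[c]
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    phi = float(np.degrees(np.arctan2(y, x)))
    if phi <= -180.0:
        phi += 360.0
    return phi


# --------------------------------------------------------------------------
# RDKit bridge
# --------------------------------------------------------------------------

def _rdkit_to_molecule(rdmol: Chem.Mol, name: str) -> Molecule:
    if rdmol.GetNumConformers() == 0:
        raise MoleculeError("no 3D coordinates")
    conf = rdmol.GetConformer()
    if not conf.Is3D():
        raise MoleculeError("no 3D coordinates")
    coords = np.array(conf.GetPositions(), dtype=float)

    atoms = []
    for a in rdmol.GetAtoms():
        sym = a.GetSymbol()
        if sym not in SUPPORTED_ELEMENTS:
            raise MoleculeError(f"element out of vocabulary: {sym}")
        atoms.append(Atom(index=a.GetIdx(), element=sym,
                          formal_charge=a.GetFormalCharge()))

    # Kekule orders for parameter lookups; aromatic flag kept separately.
    kek = Chem.Mol(rdmol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    bonds = []
    for b in rdmol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        kb = kek.GetBondBetweenAtoms(i, j)
        order_int = int(round(kb.GetBondTypeAsDouble()))
        aromatic = b.GetIsAromatic()
        bonds.append(Bond(i=i, j=j,
                          order="aromatic" if aromatic else order_int,
                          length=float(np.linalg.norm(coords[i] - coords[j])),
                          order_kekule=order_int, aromatic=aromatic))

    mol = Molecule(atoms=atoms, bonds=bonds, coordinates=coords,
                   formal_charge=int(Chem.GetFormalCharge(rdmol)), name=name)
    mol.validate()
    return mol


def to_rdkit(mol: Molecule) -> Chem.Mol:
    """Rebuild a sanitized RDKit molecule from the graph (Kekule orders)."""
    rw = Chem.RWMol()
    for a in mol.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.formal_charge)
        ra.SetNoImplicit(True)
        rw.AddAtom(ra)
    btypes = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
              3: Chem.BondType.TRIPLE}
    for b in mol.bonds:
        rw.AddBond(b.i, b.j, btypes[b.order_kekule])
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception as exc:  # pragma: no cover - defensive
        raise MoleculeError(f"perception failure: {exc}") from exc
    conf = Chem.Conformer(mol.n_atoms)
    for i, xyz in enumerate(mol.coordinates):
        conf.SetAtomPosition(i, [float(x) for x in xyz])
    out.AddConformer(conf)
    return out


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------

def read_structure(path: str, fmt: str | None = None) -> Molecule:
    """Read an SDF (V2000) or MOL2 (TRIPOS) file into a perceived Molecule.

    The file must carry explicit hydrogens and 3D coordinates; 2D->3D
    embedding and protonation are out of scope.  Multi-fragment inputs
    (salts, counter-ions) are rejected.

    Parameters
    ----------
    path : str
        Input file path.
    fmt : {"sdf", "mol2"}, optional
        Format; inferred from the extension if omitted.
    """
    path = str(path)
    if fmt is None:
        low = path.lower()
        fmt = "mol2" if low.endswith(".mol2") else "sdf"
    if fmt == "sdf":
        rdmol = Chem.MolFromMolFile(path, removeHs=False, sanitize=True)
    elif fmt == "mol2":
        rdmol = Chem.MolFromMol2File(path, removeHs=False, sanitize=True)
    else:
        raise MoleculeError(f"unsupported format: {fmt}")
    if rdmol is None:
        raise MoleculeError(f"could not parse {path} as {fmt}")
    name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
    mol = _rdkit_to_molecule(rdmol, name=name)
    return perceive_environment(mol)


def write_structure(mol: Molecule, path: str) -> None:
    """Write the molecule as an SDF V2000 file (explicit H, 3D)."""
    rdmol = to_rdkit(mol)
    rdmol.SetProp("_Name", mol.name)
    Chem.MolToMolFile(rdmol, str(path))


def from_rdkit(rdmol: Chem.Mol, name: str = "") -> Molecule:
    """Adopt an in-memory RDKit molecule (explicit H, one 3D conformer)."""
    return perceive_environment(_rdkit_to_molecule(rdmol, name=name))


_HYB_MAP = {
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
}


def perceive_environment(mol: Molecule) -> Molecule:
    """Fill hybridization, aromaticity, ring and H-bond flags for every atom.

    Perception runs on a sanitized RDKit rebuild of the graph, so the
    aromaticity model is RDKit's ring-based one.  Donor/acceptor rule:
    donor = N/O/S bearing at least one hydrogen (the hydrogen itself is
    also flagged), acceptor = any O, or any N that is not a three-connected
    aromatic (pyrrole-type) nitrogen.
    """
    mol.validate()
    rdmol = to_rdkit(mol)
    ri = rdmol.GetRingInfo()
    Chem.AssignStereochemistryFrom3D(rdmol)

    for a in mol.atoms:
        ra = rdmol.GetAtomWithIdx(a.index)
        a.electronegativity = ELECTRONEGATIVITY[a.element]
        a.covalent_radius = COVALENT_RADIUS[a.element]
        a.valence = int(ra.GetTotalValence())
        a.hybridization = _HYB_MAP.get(ra.GetHybridization(), "other")
        a.aromatic = bool(ra.GetIsAromatic())
        a.in_ring = bool(ra.IsInRing())
        a.in_fused_ring = ri.NumAtomRings(a.index) >= 2
        a.chiral = ra.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED
        a.axial = False

        nbr_elems = [n.GetSymbol() for n in ra.GetNeighbors()]
        if a.element in ("N", "O", "S"):
            a.h_donor = "H" in nbr_elems
        elif a.element == "H":
            a.h_donor = bool(nbr_elems) and nbr_elems[0] in ("N", "O", "S")
        if a.element == "O":
            a.h_acceptor = True
        elif a.element == "N":
            a.h_acceptor = not (a.aromatic and ra.GetDegree() == 3)

    for b in mol.bonds:
        rb = rdmol.GetBondBetweenAtoms(b.i, b.j)
        b.aromatic = rb.GetIsAromatic()
        b.order = "aromatic" if b.aromatic else b.order_kekule

    mol.perceived = True
    return mol


def shell_atoms(mol: Molecule, atom_index: int, k: int) -> set[int]:
    """Atoms at graph distance exactly ``k`` (1..3) from ``atom_index``.

    Shells are disjoint by construction and never contain the reference.
    """
    if k not in (1, 2, 3):
        raise MoleculeError("shell depth unsupported")
    if not (0 <= atom_index < mol.n_atoms):
        raise MoleculeError(f"atom index out of range: {atom_index}")
    lengths = nx.single_source_shortest_path_length(
        mol.graph(), atom_index, cutoff=k)
    return {idx for idx, d in lengths.items() if d == k}


def internal_coordinates(mol: Molecule) -> InternalCoordinates:
    """Enumerate all bonds, angles, and proper torsions with their values.

    Duplicates are removed under the symmetries i-j == j-i, i-j-k == k-j-i
    and a-b-c-d == d-c-b-a; the canonical representative has the smaller
    first index (for torsions, (b, c) ordered so b < c, or a < d when
    b == c cannot happen).
    """
    coords = mol.coordinates
    adj: dict[int, list[int]] = {i: [] for i in range(mol.n_atoms)}
    for b in mol.bonds:
        adj[b.i].append(b.j)
        adj[b.j].append(b.i)
    for v in adj.values():
        v.sort()

    bonds = [(b.as_tuple()[0], b.as_tuple()[1],
              distance(coords, b.i, b.j)) for b in mol.bonds]
    bonds.sort()

    angles = []
    for j in range(mol.n_atoms):
        nbrs = adj[j]
        for x in range(len(nbrs)):
            for y in range(x + 1, len(nbrs)):
                i, k = nbrs[x], nbrs[y]
                angles.append((i, j, k, angle_deg(coords, i, j, k)))
    angles.sort()

    torsions = []
    seen = set()
    for bnd in mol.bonds:
        b_, c_ = bnd.i, bnd.j
        for bb, cc in ((b_, c_), (c_, b_)):
            for a in adj[bb]:
                if a == cc:
                    continue
                for d in adj[cc]:
                    if d == bb or d == a:
                        continue
                    key = (a, bb, cc, d)
                    if key[::-1] in seen or key in seen:
                        continue
                    seen.add(key)
                    torsions.append(
                        (a, bb, cc, d, dihedral_deg(coords, a, bb, cc, d)))
    torsions.sort()
    return InternalCoordinates(bonds=bonds, angles=angles, torsions=torsions)


def graph_distance(mol: Molecule, i: int, j: int) -> int:
    """Shortest bond-path length between two atoms."""
    return nx.shortest_path_length(mol.graph(), i, j)
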