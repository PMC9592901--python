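"""Force-field topology assembly, GROMACS output, and bonded-energy checks.

Assembly follows the standard small-molecule workflow: predict (or
rule-assign) atom types -> look up Lennard-Jones parameters by type ->
predict raw partial charges -> spread the residual against the molecular
formal charge uniformly over all atoms -> optional antisymmetric bond
charge corrections -> enumerate bonds/angles/torsions with equilibrium
values taken from the input geometry -> predict force constants ->
enumerate 1-4 pairs (first and fourth atoms of proper torsions at graph
distance exactly three) and improper dihedrals (one per three-connected
sp2 carbon, planarity-preserving gamma = 180, n = 2).

Internal units are Angstrom / kcal/mol / degrees with the bonded form

    V = sum K_b (r - r0)^2 + sum K_theta (theta - theta0)^2
        + sum K_phi [1 + cos(n phi - gamma)]

(no 1/2 in the harmonic terms).  The GROMACS writer converts to nm / kJ/mol
and emits 2*K for the harmonic constants, since GROMACS uses k/2 (x-x0)^2;
AMBER-style function codes are used throughout (bonds 1, angles 1, proper
dihedrals 9, impropers 4, pairs 1, fudgeLJ 0.5, fudgeQQ 0.8333).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import gaffdata
from .atomtype_rules import assign_atom_types
from .gaffdata import ParameterTable, default_parameter_table
from .molgraph import (InternalCoordinates, Molecule, angle_deg, dihedral_deg,
                       internal_coordinates)

KCAL_TO_KJ = 4.184
A_TO_NM = 0.1
FUDGE_LJ = 0.5
FUDGE_QQ = 0.8333

#: Improper stiffness (kcal/mol): stiffer for carbonyl centers.
IMPROPER_K_DEFAULT = 1.1
IMPROPER_K_CARBONYL = 10.5


# --------------------------------------------------------------------------
# Data model
# --------------------------------------------------------------------------

@dataclass
class TopologyAtom:
    index: int
    type_code: str
    charge: float           # e
    sigma: float            # Angstrom
    epsilon: float          # kcal/mol
    mass: float             # amu
    element: str = ""


@dataclass
class Topology:
    """Complete bonded + nonbonded parameter set for one molecule."""

    name: str
    atoms: list[TopologyAtom]
    bonds: list[tuple[int, int, float, float]]            # i, j, r0 A, Kb
    angles: list[tuple[int, int, int, float, float]]      # i, j, k, th0 deg, Kth
    dihedrals: list[tuple[int, int, int, int, float, int, float]]  # gamma, n, Kphi
    impropers: list[tuple[int, int, int, int, float, int, float]]
    pairs14: list[tuple[int, int]]
    formal_charge: int = 0

    @property
    def total_charge(self) -> float:
        return float(sum(a.charge for a in self.atoms))

    def validate(self) -> None:
        n = len(self.atoms)
        if abs(self.total_charge - self.formal_charge) > 1e-6:
            raise ValueError("charge sum violates formal charge")
        for term in (self.bonds + self.angles + self.dihedrals
                     + self.impropers + self.pairs14):
            for idx in term[: {2: 2, 4: 2, 5: 3, 7: 4}[len(term)]]:
                if not (0 <= idx < n):
                    raise ValueError(f"index out of range in term {term}")


@dataclass
class BCCTable:
    """Directed bond-charge-correction increments.

    ``rules[(type_a, type_b, order)] = delta`` moves +delta onto the
    endpoint typed ``type_a`` and -delta onto the ``type_b`` endpoint;
    ``order`` is "1"/"2"/"3"/"ar" or "*" for any.
    """

    rules: dict[tuple[str, str, str], float] = field(default_factory=dict)

    @staticmethod
    def from_csv(path: str) -> "BCCTable":
        rules = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line or line.lower().startswith("type_a"):
                    continue
                parts = [p.strip() for p in line.replace(",", " ").split()]
                ta, tb, order, delta = parts[0], parts[1], parts[2], float(parts[3])
                rules[(ta, tb, order)] = delta
        return BCCTable(rules=rules)


# --------------------------------------------------------------------------
# Charge operations
# --------------------------------------------------------------------------

def normalize_charges(raw: np.ndarray, formal_charge: int) -> np.ndarray:
    """Distribute the residual (Q_formal - sum q) equally over all atoms."""
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("no atoms")
    return raw + (float(formal_charge) - raw.sum()) / raw.size


def apply_bond_charge_corrections(mol: Molecule, charges: np.ndarray,
                                  table: BCCTable,
                                  atom_types: list[str] | None = None
                                  ) -> np.ndarray:
    """Antisymmetric per-bond increments; total charge is preserved exactly.

    Raises "ambiguous BCC rule" if more than one rule matches a bond.
    """
    q = np.asarray(charges, dtype=float).copy()
    if not table.rules:
        return q
    types = atom_types if atom_types is not None else assign_atom_types(mol)
    for b in mol.bonds:
        order = "ar" if b.aromatic else str(b.order_kekule)
        matches = []
        for (ta, tb, o), delta in table.rules.items():
            if o not in (order, "*"):
                continue
            if types[b.i] == ta and types[b.j] == tb:
                matches.append((b.i, b.j, delta))
            elif types[b.j] == ta and types[b.i] == tb:
                matches.append((b.j, b.i, delta))
        if len(matches) > 1:
            raise ValueError(f"ambiguous BCC rule for bond {b.i}-{b.j}")
        if matches:
            plus, minus, delta = matches[0]
            q[plus] += delta
            q[minus] -= delta
    return q


# --------------------------------------------------------------------------
# Term enumeration
# --------------------------------------------------------------------------

def enumerate_pairs14(internal: InternalCoordinates,
                      mol: Molecule) -> list[tuple[int, int]]:
    """Unique 1-4 pairs: torsion end atoms at graph distance exactly 3.

    End atoms of a torsion that are also reachable in one or two bonds
    (small rings) are excluded, as their interaction is already covered by
    the bonded exclusions.
    """
    g = mol.graph()
    pairs = set()
    for t in internal.torsions:
        a, d = t[0], t[3]
        if nx.shortest_path_length(g, a, d) == 3:
            pairs.add((a, d) if a < d else (d, a))
    return sorted(pairs)


def enumerate_impropers(mol: Molecule
                        ) -> list[tuple[int, int, int, int, float, int, float]]:
    """One improper per three-connected sp2 carbon, central atom third."""
    out = []
    for a in mol.atoms:
        if a.element != "C" or a.hybridization != "sp2":
            continue
        nbrs = mol.neighbors(a.index)
        if len(nbrs) != 3:
            continue
        k = IMPROPER_K_DEFAULT
        for j in nbrs:
            b = mol.bond_between(a.index, j)
            if mol.atoms[j].element == "O" and b.order_kekule == 2:
                k = IMPROPER_K_CARBONYL
        out.append((nbrs[0], nbrs[1], a.index, nbrs[2], 180.0, 2, k))
    return out


# --------------------------------------------------------------------------
# Assembly
# --------------------------------------------------------------------------

def assemble_topology(mol: Molecule, bundle=None,
                      params: ParameterTable | None = None,
                      bcc: BCCTable | None = None,
                      typing: str | None = None) -> Topology:
    """Build the full Topology for one perceived molecule.

    With a trained :class:`~ffforge.mlmodels.ModelBundle` the five heads
    supply charges, types, torsion phase/periodicity and force constants;
    without one (``bundle=None``) the deterministic oracles are used
    instead (rule typing, EEM charges, reference force constants).
    ``typing="rules"`` forces rule-based types even when a bundle is given.
    """
    params = params or default_parameter_table()
    if typing is None:
        typing = "model" if bundle is not None else "rules"

    if typing == "rules" or bundle is None:
        types = assign_atom_types(mol)
    else:
        from .mlmodels import predict_atom_types
        types = predict_atom_types(bundle.atomtype, mol)

    if bundle is not None:
        from .mlmodels import predict_charges
        raw = predict_charges(bundle.charge, mol)
    else:
        from .synthdata import eem_charges
        raw = eem_charges(mol)
    charges = normalize_charges(raw, mol.formal_charge)
    if bcc is not None:
        charges = apply_bond_charge_corrections(mol, charges, bcc,
                                                atom_types=types)

    atoms = []
    for i, (a, code) in enumerate(zip(mol.atoms, types)):
        sigma, eps = params.lj_for(code)
        atoms.append(TopologyAtom(index=i, type_code=code,
                                  charge=float(charges[i]), sigma=sigma,
                                  epsilon=eps, mass=params.mass_for(code),
                                  element=a.element))

    ic = internal_coordinates(mol)
    if bundle is not None:
        from .mlmodels import predict_force_constants
        bond_k, angle_k = predict_force_constants(bundle.force_constants,
                                                  mol, ic)
    else:
        bond_k = {(i, j): gaffdata.bond_force_constant(mol, i, j)
                  for i, j, _ in ic.bonds}
        angle_k = {(i, j, k): gaffdata.angle_force_constant(mol, i, j, k)
                   for i, j, k, _ in ic.angles}

    bonds = [(i, j, r, bond_k[(i, j)]) for i, j, r in ic.bonds]
    angles = [(i, j, k, th, angle_k[(i, j, k)])
              for i, j, k, th in ic.angles]

    if bundle is not None:
        from .mlmodels import predict_torsion_params
        tparams = predict_torsion_params(bundle.phase, bundle.periodicity, mol)
    else:
        tparams = None
    dihedrals = []
    for a_, b_, c_, d_, _phi in ic.torsions:
        kphi, n_ref, gamma_ref = gaffdata.torsion_reference(mol, b_, c_,
                                                            table=params)
        if tparams is not None:
            from .descriptors import canonical_torsion
            gamma, n = tparams[canonical_torsion((a_, b_, c_, d_))]
        else:
            gamma, n = gamma_ref, n_ref
        dihedrals.append((a_, b_, c_, d_, float(gamma), int(n), kphi))

    top = Topology(name=mol.name or "MOL", atoms=atoms, bonds=bonds,
                   angles=angles, dihedrals=dihedrals,
                   impropers=enumerate_impropers(mol),
                   pairs14=enumerate_pairs14(ic, mol),
                   formal_charge=mol.formal_charge)
    top.validate()
    return top


# --------------------------------------------------------------------------
# GROMACS writer / validating reader
# --------------------------------------------------------------------------

def write_gromacs(top: Topology, path: str) -> None:
    """Write an AMBER-convention GROMACS .itp/.top (kJ, nm, k/2 harmonics)."""
    lines = []
    w = lines.append
    w("[ defaults ]")
    w("; nbfunc  comb-rule  gen-pairs  fudgeLJ  fudgeQQ")
    w(f"1  2  yes  {FUDGE_LJ}  {FUDGE_QQ}")
    w("")
    w("[ atomtypes ]")
    w("; name  at.num  mass  charge  ptype  sigma(nm)  epsilon(kJ/mol)")
    seen = set()
    for a in top.atoms:
        if a.type_code in seen:
            continue
        seen.add(a.type_code)
        w(f"{a.type_code:<6s} 0 {a.mass:10.5f} 0.000000 A "
          f"{a.sigma * A_TO_NM:.8e} {a.epsilon * KCAL_TO_KJ:.8e}")
    w("")
    w("[ moleculetype ]")
    w(f"{top.name or 'MOL'}  3")
    w("")
    w("[ atoms ]")
    w(";  nr  type  resnr  residue  atom  cgnr  charge  mass")
    for a in top.atoms:
        atom_name = f"{a.element}{a.index + 1}"
        w(f"{a.index + 1:5d} {a.type_code:<6s} 1 MOL {atom_name:<5s} "
          f"{a.index + 1:4d} {a.charge:12.8f} {a.mass:10.5f}")
    if top.bonds:
        w("")
        w("[ bonds ]")
        w(";  i  j  func  r0(nm)  kb(kJ/mol/nm2)")
        for i, j, r0, kb in top.bonds:
            w(f"{i + 1:5d} {j + 1:5d} 1 {r0 * A_TO_NM:.8e} "
              f"{2.0 * kb * KCAL_TO_KJ / A_TO_NM ** 2:.8e}")
    if top.pairs14:
        w("")
        w("[ pairs ]")
        for i, j in top.pairs14:
            w(f"{i + 1:5d} {j + 1:5d} 1")
    if top.angles:
        w("")
        w("[ angles ]")
        w(";  i  j  k  func  theta0(deg)  ktheta(kJ/mol/rad2)")
        for i, j, k, th0, kth in top.angles:
            w(f"{i + 1:5d} {j + 1:5d} {k + 1:5d} 1 {th0:.8f} "
              f"{2.0 * kth * KCAL_TO_KJ:.8e}")
    if top.dihedrals:
        w("")
        w("[ dihedrals ] ; propers, func 9")
        for i, j, k, l, gamma, n, kphi in top.dihedrals:
            w(f"{i + 1:5d} {j + 1:5d} {k + 1:5d} {l + 1:5d} 9 "
              f"{gamma:.4f} {kphi * KCAL_TO_KJ:.8e} {n:d}")
    if top.impropers:
        w("")
        w("[ dihedrals ] ; impropers, func 4")
        for i, j, k, l, gamma, n, kphi in top.impropers:
            w(f"{i + 1:5d} {j + 1:5d} {k + 1:5d} {l + 1:5d} 4 "
              f"{gamma:.4f} {kphi * KCAL_TO_KJ:.8e} {n:d}")
    if str(path).endswith(".top"):
        w("")
        w("[ system ]")
        w(top.name or "MOL")
        w("")
        w("[ molecules ]")
        w(f"{top.name or 'MOL'} 1")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gromacs(path: str) -> Topology:
    """Validating reader: parse a written .itp/.top back to internal units."""
    section = None
    dihedral_kind = "proper"
    name = "MOL"
    lj_by_type: dict[str, tuple[float, float]] = {}
    mass_by_type: dict[str, float] = {}
    atoms_raw, bonds, angles, dihedrals, impropers, pairs = [], [], [], [], [], []
    with open(path) as fh:
        for raw in fh:
            line = raw.split(";", 1)[0].strip()
            if not line:
                continue
            if line.startswith("["):
                section = line.strip("[] \t").lower()
                if section == "dihedrals":
                    dihedral_kind = None  # decided by func code
                continue
            parts = line.split()
            if section == "atomtypes":
                lj_by_type[parts[0]] = (float(parts[5]) / A_TO_NM,
                                        float(parts[6]) / KCAL_TO_KJ)
                mass_by_type[parts[0]] = float(parts[2])
            elif section == "moleculetype":
                name = parts[0]
            elif section == "atoms":
                atoms_raw.append((int(parts[0]) - 1, parts[1],
                                  float(parts[6]), float(parts[7]), parts[4]))
            elif section == "bonds":
                bonds.append((int(parts[0]) - 1, int(parts[1]) - 1,
                              float(parts[3]) / A_TO_NM,
                              float(parts[4]) * A_TO_NM ** 2 / (2 * KCAL_TO_KJ)))
            elif section == "pairs":
                pairs.append((int(parts[0]) - 1, int(parts[1]) - 1))
            elif section == "angles":
                angles.append((int(parts[0]) - 1, int(parts[1]) - 1,
                               int(parts[2]) - 1, float(parts[4]),
                               float(parts[5]) / (2 * KCAL_TO_KJ)))
            elif section == "dihedrals":
                idx = tuple(int(p) - 1 for p in parts[:4])
                func = int(parts[4])
                term = (*idx, float(parts[5]), int(parts[7]),
                        float(parts[6]) / KCAL_TO_KJ)
                (dihedrals if func == 9 else impropers).append(term)
    atoms = []
    for i, code, q, mass, atom_name in atoms_raw:
        sigma, eps = lj_by_type[code]
        element = "".join(c for c in atom_name if c.isalpha())
        atoms.append(TopologyAtom(index=i, type_code=code, charge=q,
                                  sigma=sigma, epsilon=eps, mass=mass,
                                  element=element))
    total = sum(a.charge for a in atoms)
    return Topology(name=name, atoms=atoms, bonds=bonds, angles=angles,
                    dihedrals=dihedrals, impropers=impropers, pairs14=pairs,
                    formal_charge=int(round(total)))


# --------------------------------------------------------------------------
# Bonded-energy evaluation (internal kcal/mol convention, no 1/2 factors)
# --------------------------------------------------------------------------

def evaluate_bonded_energy(top: Topology, coords: np.ndarray) -> dict[str, float]:
    """Bond/angle/dihedral energy components in kcal/mol at given coords."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(top.atoms), 3):
        raise ValueError("dimension mismatch")
    e_bond = 0.0
    for i, j, r0, kb in top.bonds:
        r = float(np.linalg.norm(coords[i] - coords[j]))
        e_bond += kb * (r - r0) ** 2
    e_angle = 0.0
    for i, j, k, th0, kth in top.angles:
        th = angle_deg(coords, i, j, k)
        e_angle += kth * math.radians(th - th0) ** 2
    e_dih = 0.0
    for i, j, k, l, gamma, n, kphi in top.dihedrals + top.impropers:
        phi = dihedral_deg(coords, i, j, k, l)
        e_dih += kphi * (1.0 + math.cos(math.radians(n * phi - gamma)))
    return {"bond": e_bond, "angle": e_angle, "dihedral": e_dih,
            "total": e_bond + e_angle + e_dih}
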