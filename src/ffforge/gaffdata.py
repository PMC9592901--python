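"""GAFF-style reference parameters: Lennard-Jones, masses, bonded constants.

Holds a compact, hand-typed table of published GAFF Lennard-Jones
parameters (R_min/2 in Angstrom, epsilon in kcal/mol) keyed by atom type,
plus reference bond / angle force constants and the cosine-series torsion
classes used both as surrogate training labels and as the dihedral-constant
source during topology assembly.  Internal units everywhere: Angstrom,
kcal/mol, degrees; conversion to GROMACS units happens only in the writer.

A user-supplied table in the simple whitespace format

    NONB <type> <rmin/2 A> <eps kcal/mol>
    MASS <type> <amu>
    BOND <el1>-<el2>:<order> <K kcal/mol/A^2>
    ANGL <el> <K kcal/mol/rad^2>
    DIHE <class> <K kcal/mol> <periodicity> <phase deg>

(read with :func:`load_parameter_table`) overrides any built-in entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .molgraph import ATOMIC_MASS, Molecule

# R_min/2 (Angstrom), epsilon (kcal/mol) — GAFF nonbonded parameters.
_LJ: dict[str, tuple[float, float]] = {}
for _t in ("c", "c2", "ca", "cc", "cd", "ce", "cf", "cp", "cq", "cu", "cv"):
    _LJ[_t] = (1.9080, 0.0860)
for _t in ("c3", "cx", "cy"):
    _LJ[_t] = (1.9080, 0.1094)
for _t in ("c1", "cg", "ch"):
    _LJ[_t] = (1.9080, 0.2100)
_LJ.update({
    "hc": (1.4870, 0.0157), "h1": (1.3870, 0.0157), "h2": (1.2870, 0.0157),
    "h3": (1.1870, 0.0157), "hx": (1.1000, 0.0157), "ha": (1.4590, 0.0150),
    "h4": (1.4090, 0.0150), "h5": (1.3590, 0.0150), "hn": (0.6000, 0.0157),
    "ho": (0.0000, 0.0000), "hs": (0.6000, 0.0157), "hp": (0.6000, 0.0157),
})
for _t in ("n", "n1", "n2", "n3", "n4", "na", "nb", "nc", "nd", "ne", "nf",
           "nh", "no"):
    _LJ[_t] = (1.8240, 0.1700)
_LJ.update({
    "o": (1.6612, 0.2100), "oh": (1.7210, 0.2104), "os": (1.6837, 0.1700),
    "p3": (2.1000, 0.2000), "p5": (2.1000, 0.2000),
    "s": (2.0000, 0.2500), "s4": (2.0000, 0.2500), "s6": (2.0000, 0.2500),
    "sh": (2.0000, 0.2500), "ss": (2.0000, 0.2500),
    "f": (1.7500, 0.0610), "cl": (1.9480, 0.2650), "br": (2.2200, 0.3200),
})

# Reference harmonic bond constants, kcal/mol/A^2, keyed by sorted element
# pair and bond class ("1"/"2"/"3"/"ar").  Representative GAFF magnitudes.
_BOND_K: dict[tuple[str, str, str], float] = {
    ("C", "C", "1"): 303.1, ("C", "C", "2"): 589.7, ("C", "C", "3"): 900.0,
    ("C", "C", "ar"): 478.4,
    ("C", "H", "1"): 337.3,
    ("C", "N", "1"): 320.6, ("C", "N", "2"): 558.4, ("C", "N", "3"): 888.0,
    ("C", "N", "ar"): 483.1,
    ("C", "O", "1"): 301.5, ("C", "O", "2"): 648.0, ("C", "O", "ar"): 386.0,
    ("C", "S", "1"): 227.0, ("C", "S", "2"): 398.0, ("C", "S", "ar"): 279.0,
    ("C", "F", "1"): 363.8, ("C", "Cl", "1"): 232.4, ("Br", "C", "1"): 196.1,
    ("C", "P", "1"): 212.0,
    ("H", "N", "1"): 434.0, ("H", "O", "1"): 369.6, ("H", "S", "1"): 274.0,
    ("H", "P", "1"): 230.0,
    ("N", "N", "1"): 383.0, ("N", "N", "2"): 549.0, ("N", "N", "ar"): 451.0,
    ("N", "O", "1"): 301.0, ("N", "O", "2"): 550.0,
    ("O", "P", "1"): 230.0, ("O", "P", "2"): 465.0,
    ("O", "S", "1"): 300.0, ("O", "S", "2"): 493.0,
    ("S", "S", "1"): 166.0,
}

# Reference harmonic angle constants, kcal/mol/rad^2, by apex element.
_ANGLE_K_APEX = {"C": 63.0, "N": 70.0, "O": 75.0, "S": 62.0, "P": 45.0,
                 "H": 35.0}

# Torsion classes by central-bond character: K_phi per path (kcal/mol),
# periodicity n, phase gamma (deg).  Planarity-preserving classes use
# gamma = 180, n = 2; saturated rotors the threefold 0-phase term.
_TORSION_CLASS = {
    "aromatic": (3.625, 2, 180.0),
    "double": (6.650, 2, 180.0),
    "conjugated": (2.500, 2, 180.0),
    "single": (0.1556, 3, 0.0),
}


def rmin_half_to_sigma(rmin_half: float) -> float:
    """sigma (same units) from R_min/2: sigma = 2*rmin_half / 2^(1/6)."""
    return 2.0 * rmin_half / (2.0 ** (1.0 / 6.0))


def element_of_type(code: str) -> str:
    """Element symbol an atom-type code belongs to."""
    if code in ("cl", "br", "f"):
        return code.capitalize() if code != "f" else "F"
    return code[0].upper()


@dataclass
class ParameterTable:
    """Atom-type keyed nonbonded (+mass) and reference bonded constants."""

    lj: dict[str, tuple[float, float]] = field(default_factory=dict)  # sigma A, eps kcal
    mass: dict[str, float] = field(default_factory=dict)
    bond_k: dict[tuple[str, str, str], float] = field(default_factory=dict)
    angle_k_apex: dict[str, float] = field(default_factory=dict)
    torsion_class: dict[str, tuple[float, int, float]] = field(default_factory=dict)

    def lj_for(self, code: str) -> tuple[float, float]:
        if code not in self.lj:
            raise KeyError(f"parameter table incomplete: {code}")
        return self.lj[code]

    def mass_for(self, code: str) -> float:
        if code in self.mass:
            return self.mass[code]
        return ATOMIC_MASS[element_of_type(code)]


def default_parameter_table() -> ParameterTable:
    return ParameterTable(
        lj={t: (rmin_half_to_sigma(r), e) for t, (r, e) in _LJ.items()},
        mass={},
        bond_k=dict(_BOND_K),
        angle_k_apex=dict(_ANGLE_K_APEX),
        torsion_class=dict(_TORSION_CLASS),
    )


def load_parameter_table(path: str,
                         base: ParameterTable | None = None) -> ParameterTable:
    """Read the whitespace table format; entries override the base table."""
    table = base if base is not None else default_parameter_table()
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            kind = parts[0].upper()
            if kind == "NONB":
                table.lj[parts[1]] = (rmin_half_to_sigma(float(parts[2])),
                                      float(parts[3]))
            elif kind == "MASS":
                table.mass[parts[1]] = float(parts[2])
            elif kind == "BOND":
                pair, order = parts[1].split(":")
                a, b = sorted(pair.split("-"))
                table.bond_k[(a, b, order)] = float(parts[2])
            elif kind == "ANGL":
                table.angle_k_apex[parts[1]] = float(parts[2])
            elif kind == "DIHE":
                table.torsion_class[parts[1]] = (float(parts[2]),
                                                 int(parts[3]), float(parts[4]))
            else:
                raise ValueError(f"unknown parameter record: {kind}")
    return table


# --------------------------------------------------------------------------
# Reference bonded constants (surrogate label functions)
# --------------------------------------------------------------------------

def _bond_class(mol: Molecule, i: int, j: int) -> str:
    b = mol.bond_between(i, j)
    if b.aromatic:
        return "ar"
    return str(b.order_kekule)


def bond_force_constant(mol: Molecule, i: int, j: int,
                        table: ParameterTable | None = None) -> float:
    """Reference K_b (kcal/mol/A^2) for a bond, by element pair and class."""
    tab = (table or default_parameter_table()).bond_k
    a, b = sorted((mol.atoms[i].element, mol.atoms[j].element))
    cls = _bond_class(mol, i, j)
    if (a, b, cls) in tab:
        return tab[(a, b, cls)]
    # graded fallback keeps K positive and monotone in bond class
    base = tab.get((a, b, "1"), 300.0)
    bump = {"1": 0.0, "ar": 160.0, "2": 280.0, "3": 560.0}[cls]
    return base + bump


def angle_force_constant(mol: Molecule, i: int, j: int, k: int,
                         table: ParameterTable | None = None) -> float:
    """Reference K_theta (kcal/mol/rad^2): apex-element base, modulated by
    the flanking atoms (hydrogen flanks soften the angle; aromatic apex
    stiffens it)."""
    tab = (table or default_parameter_table()).angle_k_apex
    apex = mol.atoms[j]
    base = tab.get(apex.element, 60.0)
    n_h = sum(1 for x in (i, k) if mol.atoms[x].element == "H")
    base -= 8.0 * n_h
    if apex.aromatic:
        base += 5.0
    return max(base, 20.0)


def central_bond_character(mol: Molecule, b: int, c: int) -> str:
    """Torsion class of the central bond b-c."""
    bond = mol.bond_between(b, c)
    if bond.aromatic:
        return "aromatic"
    if bond.order_kekule >= 2:
        return "double"
    hb = mol.atoms[b].hybridization
    hc = mol.atoms[c].hybridization
    if hb in ("sp", "sp2") and hc in ("sp", "sp2"):
        return "conjugated"
    return "single"


def torsion_reference(mol: Molecule, b: int, c: int,
                      table: ParameterTable | None = None
                      ) -> tuple[float, int, float]:
    """(K_phi kcal/mol, periodicity n, phase gamma deg) for central bond b-c."""
    tab = (table or default_parameter_table()).torsion_class
    return tab[central_bond_character(mol, b, c)]
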