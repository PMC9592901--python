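"""Deterministic GAFF-style atom typing.

Assigns each atom a type code from the GAFF vocabulary (c3 = sp3 carbon,
ca = aromatic carbon, hc = H on aliphatic carbon, ...) from its perceived
environment alone.  The rule table is an ordered first-match-wins list, so
typing is total, deterministic, and idempotent; it serves both as the label
oracle when training the atom-type classifier and as the reference
assignment when a trained model is absent.

The sp2-carbon pair codes that differ only by conjugation-path direction
(cc/cd, ce/cf) are resolved by a fixed parity convention (the atom whose
Kekule double-bond partner has the larger index gets the first code of the
pair).  Within GAFF these pairs share van der Waals parameters, so either
member keys the same nonbonded parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable

import networkx as nx

from .molgraph import Molecule, MoleculeError

#: Electron-withdrawing neighbor elements for hydrogen subtyping.
_EWD = {"N", "O", "S", "F", "Cl", "Br"}


class TypingError(MoleculeError):
    pass


@dataclass
class _Ctx:
    """Per-atom environment handed to rule predicates."""

    mol: Molecule
    idx: int

    def __post_init__(self):
        self.atom = self.mol.atoms[self.idx]
        self.nbr_idx = self.mol.neighbors(self.idx)
        self.nbrs = [self.mol.atoms[i] for i in self.nbr_idx]
        self.degree = len(self.nbr_idx)

    def bond_order(self, j: int) -> int:
        return self.mol.bond_between(self.idx, j).order_kekule

    @property
    def double_partners(self) -> list[int]:
        return [j for j in self.nbr_idx if self.bond_order(j) == 2]

    @property
    def triple_partners(self) -> list[int]:
        return [j for j in self.nbr_idx if self.bond_order(j) == 3]

    def nbr_elements(self) -> list[str]:
        return [a.element for a in self.nbrs]

    def min_ring_size(self) -> int:
        """Smallest ring containing this atom; 0 if acyclic."""
        sizes = self._ring_sizes().get(self.idx, [])
        return min(sizes) if sizes else 0

    def _ring_sizes(self) -> dict[int, list[int]]:
        cache = getattr(self.mol, "_ring_size_cache", None)
        if cache is None:
            cache = {}
            for cyc in nx.minimum_cycle_basis(self.mol.graph()):
                for node in cyc:
                    cache.setdefault(node, []).append(len(cyc))
            self.mol._ring_size_cache = cache
        return cache


Predicate = Callable[[_Ctx], bool]


@dataclass
class Rule:
    code: str
    description: str
    predicate: Predicate


def _parity_code(ctx: _Ctx, first: str, second: str) -> str:
    # deterministic tie-break inside the confusable sp2 pairs
    dp = ctx.double_partners
    if dp and dp[0] > ctx.idx:
        return first
    return second


def _is_conjugated_sp2(ctx: _Ctx) -> bool:
    """sp2/sp atom single-bonded to another sp2/sp heavy atom."""
    for j in ctx.nbr_idx:
        other = ctx.mol.atoms[j]
        if (ctx.bond_order(j) == 1 and other.element != "H"
                and other.hybridization in ("sp", "sp2")):
            return True
    return False


# --------------------------------------------------------------------------
# Per-element typing functions (each implements an ordered rule cascade)
# --------------------------------------------------------------------------

def _type_carbon(ctx: _Ctx) -> str:
    a = ctx.atom
    if a.hybridization == "sp3":
        ring = ctx.min_ring_size()
        if ring == 3:
            return "cx"
        if ring == 4:
            return "cy"
        return "c3"
    # carbonyl / thiocarbonyl carbon
    for j in ctx.double_partners:
        if ctx.mol.atoms[j].element in ("O", "S") and not a.aromatic:
            return "c"
    if a.hybridization == "sp":
        if _is_conjugated_sp2(ctx):
            return _parity_code(ctx, "cg", "ch")
        return "c1"
    if a.aromatic:
        # bridge carbon joining two aromatic rings through a non-ring bond
        for j in ctx.nbr_idx:
            bnd = ctx.mol.bond_between(ctx.idx, j)
            if (ctx.mol.atoms[j].aromatic and bnd.order_kekule >= 1
                    and not _bond_in_ring(ctx.mol, ctx.idx, j)
                    and ctx.mol.atoms[j].element == "C"):
                return "cp"
        return "ca"
    # non-aromatic sp2
    ring = ctx.min_ring_size()
    if ring == 3:
        return "cu"
    if ring == 4:
        return "cv"
    if _is_conjugated_sp2(ctx):
        if a.in_ring:
            return _parity_code(ctx, "cc", "cd")
        return _parity_code(ctx, "ce", "cf")
    return "c2"


def _type_hydrogen(ctx: _Ctx) -> str:
    if ctx.degree != 1:
        raise TypingError(f"untypeable atom {ctx.idx}: H with degree {ctx.degree}")
    parent = ctx.nbrs[0]
    if parent.element == "N":
        return "hn"
    if parent.element == "O":
        return "ho"
    if parent.element == "S":
        return "hs"
    if parent.element == "P":
        return "hp"
    if parent.element != "C":
        raise TypingError(f"untypeable atom {ctx.idx}: H on {parent.element}")
    pctx = _Ctx(ctx.mol, parent.index)
    ewd = sum(1 for el in pctx.nbr_elements() if el in _EWD)
    if parent.hybridization == "sp3":
        for j in pctx.nbr_idx:
            n = ctx.mol.atoms[j]
            if n.element == "N" and (n.formal_charge > 0
                                     or len(ctx.mol.neighbors(j)) == 4):
                return "hx"
        return {0: "hc", 1: "h1", 2: "h2", 3: "h3"}.get(ewd, "h3")
    # sp/sp2 parent (aromatic or vinylic)
    return {0: "ha", 1: "h4", 2: "h5"}.get(ewd, "h5")


def _type_nitrogen(ctx: _Ctx) -> str:
    a = ctx.atom
    if a.formal_charge > 0 and a.hybridization == "sp3":
        return "n4"
    # nitro
    o_nbrs = [j for j in ctx.nbr_idx if ctx.mol.atoms[j].element == "O"]
    if len(o_nbrs) >= 2 and ctx.double_partners:
        return "no"
    if a.hybridization == "sp" or ctx.triple_partners:
        return "n1"
    if a.aromatic:
        return "nb" if ctx.degree == 2 else "na"
    # amide: single bond to a carbonyl/thiocarbonyl carbon
    for j in ctx.nbr_idx:
        n = ctx.mol.atoms[j]
        if n.element == "C" and ctx.bond_order(j) == 1:
            jc = _Ctx(ctx.mol, j)
            if any(ctx.mol.atoms[k].element in ("O", "S")
                   for k in jc.double_partners):
                return "n"
    if ctx.double_partners:
        if a.in_ring and _is_conjugated_sp2(ctx):
            return _parity_code(ctx, "nc", "nd")
        if _is_conjugated_sp2(ctx):
            return _parity_code(ctx, "ne", "nf")
        return "n2"
    # amine attached to aromatic ring
    if any(n.aromatic for n in ctx.nbrs):
        return "nh"
    return "n3"


def _type_oxygen(ctx: _Ctx) -> str:
    if ctx.degree == 1 or ctx.double_partners:
        return "o"
    if "H" in ctx.nbr_elements():
        return "oh"
    return "os"


def _type_sulfur(ctx: _Ctx) -> str:
    if ctx.degree == 1:
        return "s"
    if "H" in ctx.nbr_elements():
        return "sh"
    if ctx.degree == 2:
        return "ss"
    if ctx.degree == 3:
        return "s4"
    return "s6"


def _type_phosphorus(ctx: _Ctx) -> str:
    return "p3" if ctx.degree <= 3 else "p5"


_DISPATCH = {
    "C": _type_carbon, "H": _type_hydrogen, "N": _type_nitrogen,
    "O": _type_oxygen, "S": _type_sulfur, "P": _type_phosphorus,
    "F": lambda ctx: "f", "Cl": lambda ctx: "cl", "Br": lambda ctx: "br",
}

#: Full emission vocabulary (superset actually reachable by the cascade).
VOCABULARY = (
    "c", "c1", "c2", "c3", "ca", "cc", "cd", "ce", "cf", "cg", "ch",
    "cp", "cq", "cu", "cv", "cx", "cy",
    "h1", "h2", "h3", "h4", "h5", "ha", "hc", "hn", "ho", "hp", "hs", "hx",
    "n", "n1", "n2", "n3", "n4", "na", "nb", "nc", "nd", "ne", "nf", "nh", "no",
    "o", "oh", "os", "p3", "p5", "s", "s4", "s6", "sh", "ss",
    "f", "cl", "br",
)


def _bond_in_ring(mol: Molecule, i: int, j: int) -> bool:
    g = mol.graph()
    g.remove_edge(i, j)
    try:
        nx.shortest_path_length(g, i, j)
        return True
    except nx.NetworkXNoPath:
        return False


def assign_atom_types(mol: Molecule) -> list[str]:
    """One GAFF-style type code per atom, deterministically.

    Requires a perceived molecule.  Raises :class:`TypingError` naming the
    offending atom if no rule matches (untypeable chemistry).
    """
    if not mol.perceived:
        raise TypingError("molecule not perceived")
    codes = []
    for idx in range(mol.n_atoms):
        el = mol.atoms[idx].element
        fn = _DISPATCH.get(el)
        if fn is None:
            raise TypingError(f"untypeable atom {idx}: element {el}")
        code = fn(_Ctx(mol, idx))
        if code not in VOCABULARY:  # pragma: no cover - cascade is closed
            raise TypingError(f"untypeable atom {idx}: rule emitted {code}")
        codes.append(code)
    return codes


#: sp2 pairs that share van der Waals parameters and are mutually
#: confusable; classifier errors inside a pair are parameter-neutral.
CONFUSABLE_PAIRS = (("cc", "cd"), ("ce", "cf"), ("cp", "cq"),
                    ("cg", "ch"), ("nc", "nd"), ("ne", "nf"))


def same_up_to_confusable(a: str, b: str) -> bool:
    if a == b:
        return True
    return any({a, b} == set(p) for p in CONFUSABLE_PAIRS)


def ruleset_json() -> str:
    """Auditable description of the ordered rule cascade."""
    rules = {
        "order": "first match wins within each element cascade",
        "C": ["cx/cy (sp3 in 3-/4-ring)", "c3 (sp3)", "c (carbonyl/thiocarbonyl)",
              "cg/ch (conjugated sp)", "c1 (sp)", "cp (aromatic bridge)",
              "ca (aromatic)", "cu/cv (sp2 in 3-/4-ring)",
              "cc/cd (conjugated ring sp2)", "ce/cf (conjugated chain sp2)",
              "c2 (sp2)"],
        "H": ["hn/ho/hs/hp (on N/O/S/P)", "hx (on C beta to N+)",
              "hc,h1,h2,h3 (on sp3 C by EWD count)",
              "ha,h4,h5 (on sp2 C by EWD count)"],
        "N": ["n4 (sp3 cation)", "no (nitro)", "n1 (sp)", "nb/na (aromatic 2-/3-conn)",
              "n (amide)", "nc/nd ne/nf n2 (sp2)", "nh (aryl amine)", "n3 (amine)"],
        "O": ["o (sp2/terminal)", "oh (hydroxyl)", "os (ether/ester)"],
        "S": ["s (terminal)", "sh (thiol)", "ss (2-conn)", "s4 (3-conn)", "s6 (4-conn)"],
        "P": ["p3 (<=3-conn)", "p5 (4-conn)"],
        "halogens": ["f", "cl", "br"],
        "ewd_elements": sorted(_EWD),
    }
    return json.dumps(rules, indent=2)
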