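"""Structure reading, perception, shells, and internal-coordinate counts."""

import numpy as np
import pytest
from rdkit import Chem

from ffforge import molgraph
from ffforge.molgraph import (Atom, Bond, Molecule, MoleculeError,
                              internal_coordinates, perceive_environment,
                              read_structure, shell_atoms, write_structure)


def _roundtrip(mol, tmp_path, name="m.sdf"):
    path = tmp_path / name
    write_structure(mol, path)
    return read_structure(str(path))


@pytest.mark.parametrize("name,n_atoms,n_heavy", [
    ("cyclopentanone", 14, 6),
    ("aniline", 14, 7),
    ("methane", 5, 1),
])
def test_read_structure_atom_counts(named_mols, tmp_path, name, n_atoms, n_heavy):
    mol = _roundtrip(named_mols[name], tmp_path)
    assert mol.n_atoms == n_atoms
    assert sum(1 for a in mol.atoms if a.element != "H") == n_heavy


def test_methane_bond_count(named_mols):
    assert len(named_mols["methane"].bonds) == 4


def test_read_rejects_multi_fragment(tmp_path):
    rd = Chem.AddHs(Chem.MolFromSmiles("C.C"))
    from rdkit.Chem import AllChem
    AllChem.EmbedMolecule(rd, randomSeed=3)  # 3D so the fragment check fires
    path = tmp_path / "frag.sdf"
    Chem.MolToMolFile(rd, str(path))
    with pytest.raises(MoleculeError, match="multi-fragment"):
        read_structure(str(path))


def test_read_rejects_2d(tmp_path):
    rd = Chem.AddHs(Chem.MolFromSmiles("CC"))
    Chem.rdDepictor.Compute2DCoords(rd)
    path = tmp_path / "flat.sdf"
    Chem.MolToMolFile(rd, str(path))
    with pytest.raises(MoleculeError, match="no 3D coordinates"):
        read_structure(str(path))


def test_unsupported_element_rejected():
    coords = np.array([[0.0, 0, 0], [1.6, 0, 0]])
    mol = Molecule(atoms=[Atom(0, "C"), Atom(1, "Si")],
                   bonds=[Bond(0, 1, 1, 1.6, 1)], coordinates=coords)
    with pytest.raises(MoleculeError, match="element out of vocabulary"):
        mol.validate()


class TestPerception:
    def test_benzene_aromatic_sp2_ring(self, named_mols):
        mol = named_mols["benzene"]
        carbons = [a for a in mol.atoms if a.element == "C"]
        assert len(carbons) == 6
        assert all(a.aromatic and a.hybridization == "sp2" and a.in_ring
                   for a in carbons)

    def test_cyclopentanone_hybridizations(self, named_mols):
        mol = named_mols["cyclopentanone"]
        carbonyl = [a for a in mol.atoms if a.element == "C"
                    and any(mol.bond_between(a.index, j).order_kekule == 2
                            for j in mol.neighbors(a.index))]
        assert len(carbonyl) == 1 and carbonyl[0].hybridization == "sp2"
        ring_sp3 = [a for a in mol.atoms if a.element == "C"
                    and a.hybridization == "sp3"]
        assert len(ring_sp3) == 4
        assert not any(a.aromatic for a in mol.atoms)

    def test_ethane_sp3_acyclic(self, named_mols):
        mol = named_mols["ethane"]
        assert all(a.hybridization == "sp3" for a in mol.atoms
                   if a.element == "C")
        assert not any(a.in_ring for a in mol.atoms)

    def test_donor_acceptor_flags(self, named_mols):
        aniline = named_mols["aniline"]
        n = next(a for a in aniline.atoms if a.element == "N")
        assert n.h_donor and n.h_acceptor
        ket = named_mols["cyclopentanone"]
        o = next(a for a in ket.atoms if a.element == "O")
        assert o.h_acceptor and not o.h_donor


class TestShells:
    def test_carbonyl_first_shell(self, named_mols):
        mol = named_mols["cyclopentanone"]
        cc = next(a.index for a in mol.atoms if a.element == "C"
                  and any(mol.atoms[j].element == "O"
                          for j in mol.neighbors(a.index)))
        shell = shell_atoms(mol, cc, 1)
        elems = sorted(mol.atoms[i].element for i in shell)
        assert elems == ["C", "C", "O"]

    def test_methane_far_shells_empty(self, named_mols):
        mol = named_mols["methane"]
        c = next(a.index for a in mol.atoms if a.element == "C")
        assert shell_atoms(mol, c, 2) == set()
        assert shell_atoms(mol, c, 3) == set()

    def test_aniline_nitrogen_third_shell(self, named_mols):
        mol = named_mols["aniline"]
        n = next(a.index for a in mol.atoms if a.element == "N")
        shell = shell_atoms(mol, n, 3)
        elems = sorted(mol.atoms[i].element for i in shell)
        assert elems == ["C", "C", "H", "H"]  # meta carbons + ortho hydrogens

    def test_shells_disjoint_exclude_reference(self, fixture_set):
        for mol in list(fixture_set)[:10]:
            for idx in range(mol.n_atoms):
                shells = [shell_atoms(mol, idx, k) for k in (1, 2, 3)]
                union = set().union(*shells)
                assert idx not in union
                assert len(union) == sum(len(s) for s in shells)

    def test_depth_out_of_range(self, named_mols):
        with pytest.raises(MoleculeError, match="shell depth unsupported"):
            shell_atoms(named_mols["methane"], 0, 4)


class TestInternalCoordinates:
    @pytest.mark.parametrize("name,nb,na,nt", [
        ("ethane", 7, 12, 9),
        ("benzene", 12, 18, 24),
    ])
    def test_counts(self, named_mols, name, nb, na, nt):
        ic = internal_coordinates(named_mols[name])
        assert (len(ic.bonds), len(ic.angles)) == (nb, na)
        assert len(ic.torsions) == nt

    def test_bent_triatomic(self):
        coords = np.array([[0.0, 0, 0], [0.96, 0, 0], [1.2, 0.9, 0]])
        mol = Molecule(atoms=[Atom(0, "O"), Atom(1, "C"), Atom(2, "O")],
                       bonds=[Bond(0, 1, 1, 0.96, 1), Bond(1, 2, 1, 0.94, 1)],
                       coordinates=coords)
        perceive_environment(mol)
        ic = internal_coordinates(mol)
        assert (len(ic.bonds), len(ic.angles), len(ic.torsions)) == (2, 1, 0)

    def test_counts_match_brute_force(self, named_mols):
        """Exhaustive path enumeration oracle on the graph."""
        import itertools
        for name in ("butane", "cyclopentanone", "aniline"):
            mol = named_mols[name]
            adj = {i: set(mol.neighbors(i)) for i in range(mol.n_atoms)}
            n_ang = sum(len(list(itertools.combinations(adj[j], 2)))
                        for j in range(mol.n_atoms))
            n_tor = 0
            for b in mol.bonds:
                n_tor += sum(1 for a in adj[b.i] - {b.j}
                             for d in adj[b.j] - {b.i} if a != d)
            ic = internal_coordinates(mol)
            assert len(ic.angles) == n_ang
            assert len(ic.torsions) == n_tor

    def test_bond_length_matches_distance(self, fixture_set):
        for mol in list(fixture_set)[:10]:
            for b in mol.bonds:
                d = np.linalg.norm(mol.coordinates[b.i] - mol.coordinates[b.j])
                assert abs(b.length - d) < 1e-6

    def test_enumeration_invariant_to_atom_order(self, named_mols, tmp_path):
        from rdkit import Chem
        from ffforge.molgraph import from_rdkit, to_rdkit
        mol = named_mols["cyclopentanone"]
        rd = to_rdkit(mol)
        order = list(range(mol.n_atoms))[::-1]
        perm = Chem.RenumberAtoms(rd, order)
        pmol = from_rdkit(perm, name="perm")
        ic, pic = internal_coordinates(mol), internal_coordinates(pmol)
        assert len(ic.bonds) == len(pic.bonds)
        assert len(ic.angles) == len(pic.angles)
        assert len(ic.torsions) == len(pic.torsions)
        # relabeled bond set must match exactly
        remap = {new: old for new, old in enumerate(order)}
        mapped = sorted(tuple(sorted((remap[i], remap[j]))) for i, j, _ in pic.bonds)
        assert mapped == sorted((i, j) for i, j, _ in ic.bonds)
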