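"""Topology assembly, GROMACS round trips, and bonded-energy evaluation."""

import math

import numpy as np
import pytest

from ffforge import synthdata
from ffforge.atomtype_rules import assign_atom_types
from ffforge.molgraph import graph_distance, internal_coordinates
from ffforge.topology import (BCCTable, Topology, TopologyAtom,
                              apply_bond_charge_corrections,
                              assemble_topology, enumerate_impropers,
                              enumerate_pairs14, evaluate_bonded_energy,
                              normalize_charges, read_gromacs, write_gromacs)


class TestNormalizeCharges:
    def test_residual_spread_uniformly(self):
        raw = np.full(14, 0.001)  # sums to +0.014, formal 0
        out = normalize_charges(raw, 0)
        assert np.allclose(out, 0.0, atol=1e-15)
        assert abs(out.sum()) < 1e-12

    def test_already_normalized_unchanged(self):
        raw = np.array([0.25, -0.75, 0.5])
        out = normalize_charges(raw, 0)
        assert np.allclose(out, raw)

    def test_cation_target(self):
        raw = np.full(10, 0.03)  # sums to 0.3, formal +1
        out = normalize_charges(raw, 1)
        assert np.allclose(out, 0.03 + 0.07)
        assert out.sum() == pytest.approx(1.0)


class TestBCC:
    def test_empty_table_identity(self, named_mols):
        mol = named_mols["ethane"]
        q = np.zeros(mol.n_atoms)
        out = apply_bond_charge_corrections(mol, q, BCCTable())
        assert np.array_equal(out, q)

    def test_single_rule_moves_antisymmetric_increment(self):
        mol = synthdata.molecule_from_smiles("CCO", name="ethanol", seed=5)
        types = assign_atom_types(mol)
        q = np.zeros(mol.n_atoms)
        table = BCCTable(rules={("c3", "oh", "1"): 0.03})
        out = apply_bond_charge_corrections(mol, q, table, atom_types=types)
        c = next(i for i, t in enumerate(types) if t == "c3"
                 and any(types[j] == "oh" for j in mol.neighbors(i)))
        o = next(i for i, t in enumerate(types) if t == "oh")
        assert out[c] == pytest.approx(0.03)
        assert out[o] == pytest.approx(-0.03)
        assert abs(out.sum()) < 1e-12

    def test_total_charge_invariant(self, named_mols):
        mol = named_mols["cyclopentanone"]
        q = synthdata.eem_charges(mol)
        table = BCCTable(rules={("c", "o", "2"): 0.05, ("c3", "hc", "1"): -0.01})
        out = apply_bond_charge_corrections(mol, q, table)
        assert abs(out.sum() - q.sum()) < 1e-12

    def test_colliding_rules_rejected(self, named_mols):
        mol = named_mols["cyclopentanone"]
        table = BCCTable(rules={("c", "o", "2"): 0.05, ("o", "c", "2"): 0.01})
        with pytest.raises(ValueError, match="ambiguous BCC rule"):
            apply_bond_charge_corrections(mol, np.zeros(mol.n_atoms), table)

    def test_csv_loader(self, tmp_path):
        path = tmp_path / "bcc.csv"
        path.write_text("type_a,type_b,order,delta\nc3,oh,1,0.03\n")
        table = BCCTable.from_csv(str(path))
        assert table.rules == {("c3", "oh", "1"): 0.03}


class TestPairs14:
    def test_butane_single_heavy_pair(self, named_mols):
        mol = named_mols["butane"]
        pairs = enumerate_pairs14(internal_coordinates(mol), mol)
        heavy = [p for p in pairs if mol.atoms[p[0]].element == "C"
                 and mol.atoms[p[1]].element == "C"]
        assert len(heavy) == 1

    def test_cyclopentane_ring_excluded(self):
        mol = synthdata.molecule_from_smiles("C1CCCC1", name="cyclopentane",
                                             seed=5)
        pairs = enumerate_pairs14(internal_coordinates(mol), mol)
        ring = {a.index for a in mol.atoms if a.element == "C"}
        assert not [p for p in pairs if set(p) <= ring]

    def test_benzene_para_pairs(self, named_mols):
        mol = named_mols["benzene"]
        pairs = enumerate_pairs14(internal_coordinates(mol), mol)
        ring = {a.index for a in mol.atoms if a.element == "C"}
        assert len([p for p in pairs if set(p) <= ring]) == 3

    def test_all_pairs_at_distance_three(self, fixture_set):
        for mol in list(fixture_set)[:10]:
            for i, j in enumerate_pairs14(internal_coordinates(mol), mol):
                assert graph_distance(mol, i, j) == 3


class TestImpropers:
    @pytest.mark.parametrize("name,count", [
        ("benzene", 6), ("cyclopentanone", 1), ("ethane", 0)])
    def test_reference_counts(self, named_mols, name, count):
        assert len(enumerate_impropers(named_mols[name])) == count

    def test_matches_brute_force_rule(self, fixture_set):
        for mol in list(fixture_set)[:15]:
            expected = sum(
                1 for a in mol.atoms
                if a.element == "C" and a.hybridization == "sp2"
                and len(mol.neighbors(a.index)) == 3)
            impropers = enumerate_impropers(mol)
            assert len(impropers) == expected
            for i, j, c, l, gamma, n, k in impropers:
                assert mol.atoms[c].element == "C"  # center third
                assert (gamma, n) == (180.0, 2)
                assert k > 0


class TestAssembly:
    def test_cyclopentanone_oracle_mode(self, named_mols):
        top = assemble_topology(named_mols["cyclopentanone"])
        assert len(top.atoms) == 14
        assert len(top.bonds) == 14
        assert len(top.impropers) == 1
        assert abs(top.total_charge) < 1e-6

    def test_aniline_types_match_rules(self, named_mols, trained_bundle):
        mol = named_mols["aniline"]
        top = assemble_topology(mol, bundle=trained_bundle, typing="rules")
        assert [a.type_code for a in top.atoms] == assign_atom_types(mol)

    def test_model_mode_charge_sum(self, named_mols, trained_bundle):
        top = assemble_topology(named_mols["cyclopentanone"],
                                bundle=trained_bundle)
        assert abs(top.total_charge) < 1e-6
        assert all(n > 0 for *_ , n, k in
                   [(0, 0, 0, 0, d[4], d[5], d[6]) for d in top.dihedrals])

    def test_missing_lj_entry_fails_loudly(self, named_mols):
        from ffforge.gaffdata import ParameterTable
        with pytest.raises(KeyError, match="parameter table incomplete"):
            assemble_topology(named_mols["methane"],
                              params=ParameterTable(lj={}))


class TestGromacsIO:
    def test_roundtrip_reproduces_topology(self, named_mols, tmp_path):
        for name in ("cyclopentanone", "benzene", "butane"):
            top = assemble_topology(named_mols[name])
            path = tmp_path / f"{name}.itp"
            write_gromacs(top, str(path))
            back = read_gromacs(str(path))
            assert len(back.atoms) == len(top.atoms)
            for a, b in zip(top.atoms, back.atoms):
                assert a.type_code == b.type_code
                assert abs(a.charge - b.charge) < 1e-6
                assert abs(a.sigma - b.sigma) < 1e-6
            for x, y in zip(top.bonds, back.bonds):
                assert x[:2] == y[:2]
                assert abs(x[2] - y[2]) < 1e-6 and abs(x[3] - y[3]) < 1e-4
            assert back.pairs14 == top.pairs14
            assert len(back.dihedrals) == len(top.dihedrals)
            assert len(back.impropers) == len(top.impropers)

    def test_atoms_block_charge_column_sums_to_zero(self, named_mols, tmp_path):
        top = assemble_topology(named_mols["cyclopentanone"])
        path = tmp_path / "cp.itp"
        write_gromacs(top, str(path))
        in_atoms, total, rows = False, 0.0, 0
        for line in path.read_text().splitlines():
            s = line.split(";")[0].strip()
            if s.startswith("["):
                in_atoms = s.strip("[] ").lower() == "atoms"
                continue
            if in_atoms and s:
                total += float(s.split()[6])
                rows += 1
        assert rows == 14
        assert abs(total) < 1e-6

    def test_benzene_six_func4_lines(self, named_mols, tmp_path):
        top = assemble_topology(named_mols["benzene"])
        path = tmp_path / "bz.itp"
        write_gromacs(top, str(path))
        func4 = [l for l in path.read_text().splitlines()
                 if len(l.split()) >= 8 and l.split()[4] == "4"]
        assert len(func4) == 6

    def test_methane_has_no_pairs_or_dihedral_sections(self, named_mols,
                                                       tmp_path):
        top = assemble_topology(named_mols["methane"])
        path = tmp_path / "me.itp"
        write_gromacs(top, str(path))
        text = path.read_text()
        assert "[ pairs ]" not in text
        assert "[ dihedrals ]" not in text


def _random_topology(rng, n_atoms=6):
    coords = rng.uniform(-3, 3, size=(n_atoms, 3))
    atoms = [TopologyAtom(i, "c3", 0.0, 3.4, 0.1, 12.0, "C")
             for i in range(n_atoms)]
    bonds, angles, dihedrals = [], [], []
    for i in range(n_atoms - 1):
        bonds.append((i, i + 1, rng.uniform(1.0, 1.8), rng.uniform(100, 600)))
    for i in range(n_atoms - 2):
        angles.append((i, i + 1, i + 2, rng.uniform(100, 120),
                       rng.uniform(30, 90)))
    for i in range(n_atoms - 3):
        dihedrals.append((i, i + 1, i + 2, i + 3,
                          float(rng.choice([0.0, 180.0])),
                          int(rng.choice([1, 2, 3])), rng.uniform(0.1, 5.0)))
    return Topology(name="rnd", atoms=atoms, bonds=bonds, angles=angles,
                    dihedrals=dihedrals, impropers=[], pairs14=[]), coords


def _oracle_energy(top, coords):
    """Independent per-term evaluation with its own geometry code."""
    def vec(i, j):
        return coords[j] - coords[i]

    e_b = sum(k * (np.linalg.norm(vec(i, j)) - r0) ** 2
              for i, j, r0, k in top.bonds)
    e_a = 0.0
    for i, j, k_, th0, kth in top.angles:
        u, v = vec(j, i), vec(j, k_)
        cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        th = math.degrees(math.acos(max(-1.0, min(1.0, cos))))
        e_a += kth * math.radians(th - th0) ** 2
    e_d = 0.0
    for i, j, k_, l, gamma, n, kphi in top.dihedrals + top.impropers:
        b1, b2, b3 = vec(i, j), vec(j, k_), vec(k_, l)
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        cos = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
        phi = math.degrees(math.acos(max(-1.0, min(1.0, cos))))
        if np.dot(np.cross(n1, n2), b2) < 0:
            phi = -phi
        e_d += kphi * (1 + math.cos(math.radians(n * phi - gamma)))
    return e_b + e_a + e_d


class TestBondedEnergy:
    def test_zero_at_equilibrium_geometry(self, named_mols):
        mol = named_mols["cyclopentanone"]
        top = assemble_topology(mol)
        e = evaluate_bonded_energy(top, mol.coordinates)
        assert e["bond"] == pytest.approx(0.0, abs=1e-10)
        assert e["angle"] == pytest.approx(0.0, abs=1e-10)

    def test_single_dihedral_closed_form(self):
        coords = np.array([[0.0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]])
        atoms = [TopologyAtom(i, "c3", 0.0, 3.4, 0.1, 12.0, "C")
                 for i in range(4)]
        top = Topology(name="t", atoms=atoms, bonds=[], angles=[],
                       dihedrals=[(0, 1, 2, 3, 180.0, 2, 1.0)],
                       impropers=[], pairs14=[])
        # cis geometry: phi = 0, so K[1 + cos(-180)] = 0
        e = evaluate_bonded_energy(top, coords)
        assert e["dihedral"] == pytest.approx(0.0, abs=1e-12)

    def test_stretched_bond_quadratic(self):
        coords = np.array([[0.0, 0, 0], [1.6, 0, 0]])
        atoms = [TopologyAtom(i, "c3", 0.0, 3.4, 0.1, 12.0, "C")
                 for i in range(2)]
        top = Topology(name="t", atoms=atoms, bonds=[(0, 1, 1.5, 300.0)],
                       angles=[], dihedrals=[], impropers=[], pairs14=[])
        e = evaluate_bonded_energy(top, coords)
        assert e["bond"] == pytest.approx(3.0, abs=1e-10)

    def test_agrees_with_independent_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            top, coords = _random_topology(rng, n_atoms=int(rng.integers(4, 9)))
            e = evaluate_bonded_energy(top, coords)
            assert abs(e["total"] - _oracle_energy(top, coords)) < 1e-8

    def test_dimension_mismatch_rejected(self, named_mols):
        top = assemble_topology(named_mols["methane"])
        with pytest.raises(ValueError, match="dimension mismatch"):
            evaluate_bonded_energy(top, np.zeros((3, 3)))
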