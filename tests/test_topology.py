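import json
import math

import numpy as np
import pytest

from ffcondense.errors import ConfigurationError, DegenerateGeometryError, StructureError
from ffcondense.topology import (
    Atom,
    Conformer,
    DEFAULT_IMPROPER_PATTERNS,
    ImproperPattern,
    MoleculeTopology,
    detect_impropers,
    enumerate_internals,
    measure,
    read_structure,
    write_mol2,
    write_sdf,
)

WATER_MOL2 = """@<TRIPOS>MOLECULE
waterish
3 2 0 0 0
SMALL
USER_CHARGES
@<TRIPOS>ATOM
1 O1 0.0000 0.0000 0.0000 6 1 waterish -0.8000
2 H2 0.9600 0.0000 0.0000 21 1 waterish 0.4000
3 H3 -0.2403 0.9294 0.0000 21 1 waterish 0.4000
@<TRIPOS>BOND
1 1 2 1
2 1 3 1
"""


def _chain(n):
    return MoleculeTopology(
        [Atom("C", 0, 1) for _ in range(n)],
        [(i, i + 1, 1) for i in range(n - 1)],
    )


class TestStructureIO:
    def test_mol2_water_roundtrip_is_identity(self, tmp_path):
        p = tmp_path / "w.mol2"
        p.write_text(WATER_MOL2)
        mol, conf = read_structure(str(p), "mol2")
        assert mol.n_atoms == 3 and len(mol.bonds) == 2
        assert [a.element for a in mol.atoms] == ["O", "H", "H"]
        assert [a.atom_type_id for a in mol.atoms] == [6, 21, 21]
        np.testing.assert_array_equal(conf.coords[1], [0.96, 0.0, 0.0])

        out = tmp_path / "out.mol2"
        write_mol2(mol, conf, str(out))
        mol2, conf2 = read_structure(str(out), "mol2")
        assert [(a.element, a.atom_type_id) for a in mol2.atoms] == [
            (a.element, a.atom_type_id) for a in mol.atoms
        ]
        assert mol2.bonds == mol.bonds
        np.testing.assert_allclose(conf2.coords, conf.coords, atol=5e-5)

    def test_mol2_bond_index_out_of_range_is_structural_error(self, tmp_path):
        bad = WATER_MOL2.replace("1 1 2 1", "1 0 2 1")
        p = tmp_path / "bad.mol2"
        p.write_text(bad)
        with pytest.raises(StructureError):
            read_structure(str(p), "mol2")

    def test_mol2_malformed_atom_names_line(self, tmp_path):
        bad = WATER_MOL2.replace(
            "2 H2 0.9600 0.0000 0.0000 21 1 waterish 0.4000",
            "2 H2 xx 0.0000 0.0000 21 1 waterish 0.4000",
        )
        p = tmp_path / "bad.mol2"
        p.write_text(bad)
        from ffcondense.errors import ParseError

        with pytest.raises(ParseError, match=r":8"):
            read_structure(str(p), "mol2")

    def test_mol2_count_mismatch_is_structural_error(self, tmp_path):
        bad = WATER_MOL2.replace("3 2 0 0 0", "4 2 0 0 0")
        p = tmp_path / "bad.mol2"
        p.write_text(bad)
        with pytest.raises(StructureError, match="declares 4 atoms"):
            read_structure(str(p), "mol2")

    def test_sdf_ethane_has_seven_bonds(self, tmp_path):
        from ffcondense.fixtures import make_toy_molecule

        mol, conf, _ = make_toy_molecule("ethane")
        p = tmp_path / "ethane.sdf"
        write_sdf(mol, conf, str(p))
        mol2, conf2 = read_structure(str(p), "sdf")
        assert mol2.n_atoms == 8 and len(mol2.bonds) == 7
        np.testing.assert_allclose(conf2.coords, conf.coords, atol=5e-5)

    def test_sdf_agrees_with_rdkit(self, tmp_path):
        rdkit = pytest.importorskip("rdkit")
        from rdkit import Chem
        from ffcondense.fixtures import make_toy_molecule

        mol, conf, _ = make_toy_molecule("ethane")
        p = tmp_path / "ethane.sdf"
        write_sdf(mol, conf, str(p))
        ref = Chem.MolFromMolFile(str(p), sanitize=False, removeHs=False)
        assert ref.GetNumAtoms() == 8 and ref.GetNumBonds() == 7
        ours, _ = read_structure(str(p), "sdf")
        assert [a.element for a in ours.atoms] == [
            at.GetSymbol() for at in ref.GetAtoms()
        ]

    def test_sidecar_types(self, tmp_path):
        from ffcondense.fixtures import make_toy_molecule

        mol, conf, _ = make_toy_molecule("water_like")
        sp = tmp_path / "w.sdf"
        write_sdf(mol, conf, str(sp))
        sc = tmp_path / "types.json"
        sc.write_text(json.dumps([6, 21, 21]))
        mol2, _ = read_structure(str(sp), "sdf", "sidecar", str(sc))
        assert [a.atom_type_id for a in mol2.atoms] == [6, 21, 21]

    def test_disconnected_molecule_rejected(self):
        with pytest.raises(StructureError, match="disconnected"):
            MoleculeTopology([Atom("C"), Atom("C"), Atom("C")], [(0, 1, 1)])

    @pytest.mark.parametrize(
        "bonds", [[(0, 0, 1)], [(0, 1, 1), (1, 0, 1)], [(0, 5, 1)]]
    )
    def test_invalid_bond_lists_rejected(self, bonds):
        with pytest.raises(StructureError):
            MoleculeTopology([Atom("C"), Atom("C")], bonds)


class TestEnumeration:
    @pytest.mark.parametrize(
        "n,expect",
        [(2, (1, 0, 0)), (3, (2, 1, 0)), (4, (3, 2, 1)), (6, (5, 4, 3))],
    )
    def test_linear_chain_counts(self, n, expect):
        ic = enumerate_internals(_chain(n))
        assert (len(ic.bonds), len(ic.angles), len(ic.propers)) == expect

    def test_star_center(self):
        mol = MoleculeTopology(
            [Atom("N", 0, 8)] + [Atom("H", 0, 23)] * 3,
            [(0, i, 1) for i in (1, 2, 3)],
        )
        ic = enumerate_internals(mol)
        assert (len(ic.bonds), len(ic.angles), len(ic.propers)) == (3, 3, 0)
        assert ic.impropers == [(0, 1, 2, 3)]

    def test_counts_match_bruteforce_on_random_trees(self, rng):
        """Angle/proper counts equal a brute-force path enumeration."""
        for trial in range(25):
            n = int(rng.integers(3, 13))
            # random tree: attach node i to a random earlier node
            bonds = [(int(rng.integers(0, i)), i, 1) for i in range(1, n)]
            # sprinkle extra edges to create cycles
            for _ in range(int(rng.integers(0, 3))):
                i, j = sorted(rng.choice(n, size=2, replace=False).tolist())
                if all({i, j} != {a, b} for a, b, _ in bonds):
                    bonds.append((i, j, 1))
            mol = MoleculeTopology([Atom("C", 0, 1) for _ in range(n)], bonds)
            adj = {k: set() for k in range(n)}
            for a, b, _ in mol.bonds:
                adj[a].add(b)
                adj[b].add(a)
            bf_angles = sum(
                1 for j in range(n) for i in adj[j] for k in adj[j] if i < k
            )
            bf_propers = (
                sum(
                    1
                    for j in range(n)
                    for k in adj[j]
                    for i in adj[j]
                    for l in adj[k]
                    if i != k and l != j and i != l
                )
                // 2
            )
            ic = enumerate_internals(mol)
            assert len(ic.angles) == bf_angles
            assert len(ic.propers) == bf_propers
            assert len(set(ic.angles)) == len(ic.angles)
            assert len(set(ic.propers)) == len(ic.propers)


class TestImpropers:
    def test_trigonal_matches_tetrahedral_does_not(self):
        tri = MoleculeTopology(
            [Atom("N")] + [Atom("H")] * 3, [(0, i, 1) for i in (1, 2, 3)]
        )
        tet = MoleculeTopology(
            [Atom("C")] + [Atom("H")] * 4, [(0, i, 1) for i in (1, 2, 3, 4)]
        )
        pat = [ImproperPattern("N", 3)]
        assert detect_impropers(tri, pat) == [(0, 1, 2, 3)]
        assert detect_impropers(tet, pat) == []

    def test_two_centers_sorted_by_center_index(self):
        # H2N-NH2 style: two trigonal N centers
        mol = MoleculeTopology(
            [Atom("N"), Atom("N")] + [Atom("H")] * 4,
            [(0, 1, 1), (0, 2, 1), (0, 3, 1), (1, 4, 1), (1, 5, 1)],
        )
        imps = detect_impropers(mol, [ImproperPattern("N", 3)])
        assert imps == [(0, 1, 2, 3), (1, 0, 4, 5)]

    @pytest.mark.parametrize("bad", ["N", "N:4", "X:3", "n:3"])
    def test_invalid_patterns_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            ImproperPattern.parse(bad)

    def test_pattern_string_parsing(self):
        assert ImproperPattern.parse("C:3") == ImproperPattern("C", 3)
        assert DEFAULT_IMPROPER_PATTERNS[0].element == "N"


class TestMeasure:
    def setup_method(self):
        self.c = Conformer(
            np.array(
                [[0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.0, -1.0, 0.0]]
            )
        )

    def test_distance(self):
        c = Conformer(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 2.0]]))
        assert measure(c, "distance", (0, 1)) == pytest.approx(2.0)
        assert measure(c, "distance", (1, 0)) == pytest.approx(2.0)

    def test_right_angle(self):
        c = Conformer(np.array([[1.0, 0, 0], [0.0, 0, 0], [0.0, 1.0, 0]]))
        assert measure(c, "angle", (0, 1, 2)) == pytest.approx(math.pi / 2)

    def test_trans_and_cis_dihedrals(self):
        assert measure(self.c, "dihedral", (0, 1, 2, 3)) == pytest.approx(math.pi)
        cis = Conformer(self.c.coords.copy())
        cis.coords[3] = [1.0, 1.0, 0.0]
        assert measure(cis, "dihedral", (0, 1, 2, 3)) == pytest.approx(0.0)

    def test_dihedral_reversal_and_mirror_symmetries(self, rng):
        # traversing the chain backwards preserves the signed dihedral;
        # a mirror reflection negates it (away from the +-pi branch point)
        for _ in range(20):
            x = Conformer(rng.standard_normal((4, 3)) * 2)
            try:
                a = measure(x, "dihedral", (0, 1, 2, 3))
                b = measure(x, "dihedral", (3, 2, 1, 0))
                m = measure(
                    Conformer(x.coords * np.array([1.0, 1.0, -1.0])),
                    "dihedral",
                    (0, 1, 2, 3),
                )
            except DegenerateGeometryError:
                continue
            assert a == pytest.approx(b, abs=1e-12)
            if abs(abs(a) - math.pi) > 1e-9:
                assert m == pytest.approx(-a, abs=1e-12)

    def test_oop_zero_for_coplanar(self):
        flat = Conformer(
            np.array([[1.0, 0, 0], [0.0, 0, 0], [0, 1.0, 0], [-1.0, -1.0, 0]])
        )
        assert measure(flat, "oop", (0, 1, 2, 3)) == pytest.approx(0.0)

    def test_oop_sign_and_range(self):
        bent = Conformer(
            np.array([[1.0, 0, 0], [0.0, 0, 0], [0, 1.0, 0], [0.0, 0.0, 1.0]])
        )
        chi = measure(bent, "oop", (0, 1, 2, 3))
        assert chi == pytest.approx(math.pi / 2)

    def test_degenerate_angle_raises(self):
        c = Conformer(np.zeros((3, 3)))
        with pytest.raises(DegenerateGeometryError):
            measure(c, "angle", (0, 1, 2))
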