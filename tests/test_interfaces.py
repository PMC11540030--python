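"""Contacts, contact categories, SASA and buried surface area."""

import math

import numpy as np
import pytest

from resistoscope.interfaces import (
    ContactRecord,
    buried_surface_area,
    classify_contact,
    contact_overlap,
    find_contacts,
    residue_pair_min_distance,
    shrake_rupley_sasa,
)
from resistoscope.structure_io import Assembly, Atom, Residue
from resistoscope.synthetic_data import FixtureSpec, make_cyclic_fixture

from conftest import brute_force_contacts, make_random_dimer


def two_residue_assembly(d):
    """Two single-atom residues on different chains at distance d."""
    return Assembly(
        "pair",
        ["A", "B"],
        [
            Residue("A", 1, "", "GLY", [Atom("CA", "C", [0, 0, 0])]),
            Residue("B", 1, "", "GLY", [Atom("CA", "C", [d, 0, 0])]),
        ],
    )


class TestFindContacts:
    def test_far_apart_not_listed(self):
        asm = two_residue_assembly(10.0)
        assert find_contacts(asm, "A", "B", cutoff=5.0).contacts == []

    def test_planted_pair_listed_with_exact_distance(self, c6_assembly):
        assembly, _, truth = c6_assembly
        summary = find_contacts(assembly, "A", "B", cutoff=5.0)
        [res_a, res_b, d] = truth["planted_contacts"][0]
        hits = [
            c for c in summary.contacts if (c.res_a[1], c.res_b[1]) == (res_a, res_b)
        ]
        assert len(hits) == 1
        assert hits[0].min_dist == pytest.approx(d, abs=0.01)

    @pytest.mark.parametrize("cutoff", [4.5, 5.0])
    def test_matches_brute_force_on_random_fixtures(self, cutoff):
        """k-d tree search is exact: identical pairs and distances to all-pairs."""
        for seed in range(20):
            asm = make_random_dimer(seed)
            oracle = brute_force_contacts(asm, "A", "B", cutoff)
            summary = find_contacts(asm, "A", "B", cutoff=cutoff)
            got = {(c.res_a[:3], c.res_b[:3]): c.min_dist for c in summary.contacts}
            assert got.keys() == oracle.keys()
            for k in oracle:
                assert got[k] == pytest.approx(oracle[k], abs=1e-9)

    def test_cutoff_monotonicity(self):
        for seed in range(5):
            asm = make_random_dimer(seed)
            small = find_contacts(asm, "A", "B", cutoff=4.5).pair_keys()
            large = find_contacts(asm, "A", "B", cutoff=5.0).pair_keys()
            assert small <= large

    def test_cn_equivariance(self, c6_assembly):
        """In an ideal ring every adjacent-chain interface is identical."""
        assembly, _, _ = c6_assembly
        reference = None
        for k in range(6):
            a, b = assembly.chains[k], assembly.chains[(k + 1) % 6]
            summary = find_contacts(assembly, a, b, cutoff=5.0)
            key = sorted(
                ((c.res_a[1], c.res_b[1], round(c.min_dist, 6)) for c in summary.contacts)
            )
            if reference is None:
                reference = key
            assert key == reference

    def test_unknown_chain_errors(self, c6_assembly):
        assembly, _, _ = c6_assembly
        with pytest.raises(KeyError, match="unknown chain"):
            find_contacts(assembly, "A", "Z")


class TestPairDistance:
    def test_exact_engineered_distance(self):
        asm = two_residue_assembly(3.25)
        d, pair = residue_pair_min_distance(asm, ("A", 1), ("B", 1), atom_scope="all_heavy")
        assert d == pytest.approx(3.25, abs=1e-12)
        assert pair == ("CA", "CA")

    def test_same_residue_rejected(self, c6_assembly):
        assembly, _, _ = c6_assembly
        with pytest.raises(ValueError, match="distinct"):
            residue_pair_min_distance(assembly, ("A", 10), ("A", 10))

    def test_absent_residue_named(self, c6_assembly):
        assembly, _, _ = c6_assembly
        with pytest.raises(KeyError, match="999"):
            residue_pair_min_distance(assembly, ("A", 10), ("B", 999))


class TestClassification:
    def _record(self, name_a, atom_a, name_b, atom_b, d):
        return ContactRecord(
            res_a=("A", 1, "", name_a),
            res_b=("B", 2, "", name_b),
            min_dist=d,
            atom_pair=(atom_a, atom_b),
            category="",
        )

    @pytest.mark.parametrize(
        "rec,expected",
        [
            (("ASP", "OD1", "ARG", "NH1", 2.9), "salt_bridge"),
            (("GLU", "OE2", "LYS", "NZ", 3.9), "salt_bridge"),
            (("ASP", "OD1", "ARG", "NH1", 4.5), "nonpolar"),  # beyond 4.0
            (("SER", "OG", "THR", "OG1", 3.2), "polar"),
            (("ALA", "CB", "LEU", "CD1", 3.5), "nonpolar"),
            (("ASP", "CB", "ARG", "CZ", 3.0), "nonpolar"),  # wrong atoms for a bridge
        ],
    )
    def test_rule_application(self, rec, expected):
        assert classify_contact(self._record(*rec)) == expected

    def test_salt_bridge_detected_from_full_geometry(self):
        """Category in find_contacts uses all side-chain atoms, not just the min pair."""
        res_a = Residue(
            "A", 1, "", "ASP",
            [Atom("CB", "C", [0, 0, 0]), Atom("OD1", "O", [1.3, 0, 0])],
        )
        res_b = Residue(
            "B", 1, "", "ARG",
            [Atom("CZ", "C", [2.3, 0, 0]), Atom("NH1", "N", [4.0, 0, 0])],
        )
        asm = Assembly("sb", ["A", "B"], [res_a, res_b])
        (contact,) = find_contacts(asm, "A", "B", cutoff=5.0).contacts
        # nearest pair is CB-CZ (carbon), but OD1-NH1 at 2.7 A makes it a salt bridge
        assert contact.category == "salt_bridge"


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        one = Assembly("c", ["A"], [Residue("A", 1, "", "ALA", [Atom("C1", "C", [0, 0, 0])])])
        area = shrake_rupley_sasa(one).sum()
        exact = 4 * math.pi * (1.70 + 1.4) ** 2
        assert abs(area - exact) / exact < 0.02

    def test_far_apart_atoms_additive(self):
        asm = Assembly(
            "c2",
            ["A"],
            [
                Residue("A", 1, "", "ALA", [Atom("C1", "C", [0, 0, 0])]),
                Residue("A", 2, "", "ALA", [Atom("O1", "O", [50, 0, 0])]),
            ],
        )
        areas = shrake_rupley_sasa(asm)
        assert areas[0] == pytest.approx(4 * math.pi * 3.1**2, rel=0.02)
        assert areas[1] == pytest.approx(4 * math.pi * (1.52 + 1.4) ** 2, rel=0.02)

    def test_caged_atom_buried(self):
        # central atom enclosed by a tight shell of neighbours
        from resistoscope.interfaces import _sphere_points

        shell = [Atom(f"C{i}", "C", 2.5 * p) for i, p in enumerate(_sphere_points(60))]
        residues = [Residue("A", 1, "", "ALA", [Atom("CX", "C", [0, 0, 0])] + shell)]
        asm = Assembly("cage", ["A"], residues)
        areas = shrake_rupley_sasa(asm)
        assert areas[0] < 1.0  # central atom ~fully occluded

    def test_unknown_element_listed(self):
        asm = Assembly("u", ["A"], [Residue("A", 1, "", "UNK", [Atom("X", "XX", [0, 0, 0])])])
        with pytest.raises(ValueError, match="XX"):
            shrake_rupley_sasa(asm)

    def test_agrees_with_independent_implementation(self, c6_assembly):
        """Cross-check against biotite's Shrake-Rupley on one protomer."""
        import biotite.structure as struc

        assembly, _, _ = c6_assembly
        sub = assembly.subset_chains(["A"])
        refs = [(r, a) for r in sub.residues for a in r.atoms]
        arr = struc.AtomArray(len(refs))
        for i, (r, a) in enumerate(refs):
            arr.coord[i] = a.pos
            arr.chain_id[i] = r.chain_id
            arr.res_id[i] = r.number
            arr.res_name[i] = r.name
            arr.atom_name[i] = a.name
            arr.element[i] = a.element
        ours = shrake_rupley_sasa(sub, n_points=960).sum()
        theirs = struc.sasa(arr, point_number=960, vdw_radii="Single").sum()
        assert ours == pytest.approx(theirs, rel=0.05)


class TestBsa:
    def test_non_touching_chains_zero(self):
        asm = two_residue_assembly(50.0)
        assert buried_surface_area(asm, ["A"], ["B"]) == pytest.approx(0.0, abs=1e-9)

    def test_touching_dimer_positive_and_symmetric(self, c6_assembly):
        assembly, _, _ = c6_assembly
        ab = buried_surface_area(assembly, ["A"], ["B"], n_points=240)
        ba = buried_surface_area(assembly, ["B"], ["A"], n_points=240)
        assert ab > 0
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_matches_dense_sampling_oracle(self):
        asm = two_residue_assembly(3.0)  # overlapping expanded spheres
        coarse = buried_surface_area(asm, ["A"], ["B"], n_points=960)
        dense = buried_surface_area(asm, ["A"], ["B"], n_points=8000)
        assert coarse == pytest.approx(dense, rel=0.02)

    def test_overlapping_groups_rejected(self, c6_assembly):
        assembly, _, _ = c6_assembly
        with pytest.raises(ValueError, match="overlap"):
            buried_surface_area(assembly, ["A", "B"], ["B", "C"])


class TestContactOverlap:
    def _summary(self, pairs):
        contacts = [
            ContactRecord(("A", p, "", "ALA"), ("B", q, "", "ALA"), 3.0, ("CA", "CA"), "nonpolar")
            for p, q in pairs
        ]
        return type(
            "S", (), {"pair_keys": lambda self=None: {c.pair_key for c in contacts}}
        )()

    def test_identical_sets(self):
        s = self._summary([(1, 2), (3, 4)])
        out = contact_overlap(s, s)
        assert out["recovered_fraction"] == 1.0 and out["jaccard"] == 1.0

    def test_disjoint_sets(self):
        out = contact_overlap(self._summary([(1, 2)]), self._summary([(5, 6)]))
        assert out["jaccard"] == 0.0

    def test_partial_overlap_arithmetic(self):
        a = self._summary([(i, i + 100) for i in range(1, 11)])  # p1..p10
        b = self._summary([(i, i + 100) for i in range(1, 9)] + [(50, 60), (51, 61)])
        out = contact_overlap(a, b)
        assert out["recovered_fraction"] == pytest.approx(0.8)
        assert out["jaccard"] == pytest.approx(8 / 12)
        assert len(out["only_a"]) == 2 and len(out["only_b"]) == 2
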