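"""Kabsch fits, cyclic chain pairing, iterative pruning, module rotations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from resistoscope.structure_io import Assembly, Atom, Residue
from resistoscope.superposition import (
    centroid_angle,
    kabsch_superpose,
    module_rotation_angle,
    pair_chains_cyclically,
    pruned_match_align,
)
from resistoscope.synthetic_data import FixtureSpec, make_cyclic_fixture, make_two_state_fixture


def chain_from_coords(coords, chain_id="A", displace=None):
    residues = []
    for i, p in enumerate(coords):
        pos = np.array(p, dtype=float)
        if displace is not None and i in displace:
            pos = pos + displace[i]
        residues.append(Residue(chain_id, i + 1, "", "ALA", [Atom("CA", "C", pos)]))
    return residues


class TestKabsch:
    def test_identical_sets_zero(self):
        pts = np.random.default_rng(0).uniform(-10, 10, size=(20, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd_all < 1e-12
        assert res.transform.angle < 1e-6

    def test_known_90_degree_rotation(self):
        pts = np.random.default_rng(1).uniform(-10, 10, size=(15, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        res = kabsch_superpose(pts, pts @ R.T)
        assert res.rmsd_all < 1e-9
        assert res.transform.angle == pytest.approx(90.0, abs=1e-9)
        assert abs(res.transform.screw_axis[2]) == pytest.approx(1.0, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_transform_recovery_zero_noise(self, seed):
        """Any planted rigid motion is recovered to machine precision."""
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-10, 10, size=(10, 3))
        R = Rotation.random(random_state=seed).as_matrix()
        t = rng.uniform(-5, 5, 3)
        res = kabsch_superpose(pts, pts @ R.T + t)
        planted = np.degrees(
            np.arccos(np.clip((np.trace(R) - 1) / 2, -1, 1))
        )
        assert res.transform.angle == pytest.approx(planted, abs=1e-6)
        assert res.rmsd_all < 1e-9

    def test_noise_recovery(self):
        rng = np.random.default_rng(42)
        pts = rng.uniform(-10, 10, size=(10, 3))
        R = Rotation.from_euler("y", 37, degrees=True).as_matrix()
        noisy = pts @ R.T + rng.normal(0, 0.1, size=pts.shape)
        res = kabsch_superpose(pts, noisy)
        assert res.transform.angle == pytest.approx(37.0, abs=1.0)
        assert res.rmsd_all < 0.3  # ~ sigma*sqrt(3) scale

    def test_symmetry_of_rmsd_and_angle(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(-10, 10, (12, 3))
        b = a @ Rotation.from_euler("x", 55, degrees=True).as_matrix().T + rng.normal(0, 0.5, (12, 3))
        ab, ba = kabsch_superpose(a, b), kabsch_superpose(b, a)
        assert ab.rmsd_all == pytest.approx(ba.rmsd_all, abs=1e-9)
        assert ab.transform.angle == pytest.approx(ba.transform.angle, abs=1e-6)

    def test_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(ValueError, match="at least 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[float(i), 0, 0] for i in range(5)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)


class TestCyclicPairing:
    def test_recovers_known_shift(self, c6_assembly):
        assembly, _, _ = c6_assembly
        shifted = Assembly(
            "shifted", assembly.chains[2:] + assembly.chains[:2], assembly.residues
        )
        mapping, res = pair_chains_cyclically(shifted, assembly)
        assert res.rmsd_all < 1e-9
        assert mapping[shifted.chains[0]] == shifted.chains[0]

    def test_self_pairing_is_identity(self, c6_assembly):
        assembly, _, _ = c6_assembly
        mapping, res = pair_chains_cyclically(assembly, assembly)
        assert mapping == {c: c for c in assembly.chains}
        assert res.rmsd_all < 1e-12

    def test_best_shift_beats_all_others(self):
        a, _, _ = make_cyclic_fixture(FixtureSpec(seed=21, noise_sigma=0.2))
        b, _, _ = make_cyclic_fixture(FixtureSpec(seed=22, noise_sigma=0.2))
        mapping, best = pair_chains_cyclically(a, b)
        # exhaustive oracle over all 12 correspondences
        from resistoscope.superposition import _paired_ca

        n = len(a.chains)
        rmsds = []
        for order in (list(b.chains), list(reversed(b.chains))):
            for shift in range(n):
                m = {a.chains[k]: order[(k + shift) % n] for k in range(n)}
                pa, pb, _ = _paired_ca(a, b, m)
                rmsds.append(kabsch_superpose(pa, pb).rmsd_all)
        assert best.rmsd_all == pytest.approx(min(rmsds), abs=1e-12)

    def test_unequal_counts_error(self, c6_assembly):
        assembly, _, _ = c6_assembly
        five, _, _ = make_cyclic_fixture(FixtureSpec(seed=1, n_chains=5))
        with pytest.raises(ValueError, match="mismatch"):
            pair_chains_cyclically(assembly, five)


class TestPrunedAlign:
    def test_identical_structures_nothing_pruned(self, c6_assembly):
        assembly, _, _ = c6_assembly
        res = pruned_match_align(assembly, assembly)
        assert res.rmsd_pruned < 1e-12
        assert res.n_retained == res.n_matched

    def test_displaced_residues_are_pruned(self):
        rng = np.random.default_rng(14)
        coords = rng.uniform(-20, 20, size=(50, 3))
        displaced = {i: np.array([10.0, 0, 0]) for i in range(0, 50, 10)}  # 10%
        fixed = Assembly("f", ["A"], chain_from_coords(coords))
        moving = Assembly("m", ["A"], chain_from_coords(coords, displace=displaced))
        res = pruned_match_align(moving, fixed, prune_cutoff=2.0)
        assert res.n_matched - res.n_retained == len(displaced)
        assert res.rmsd_pruned < 1e-6
        assert res.rmsd_all > 1.0
        pruned_ids = {
            la[1] for la, _, d in res.pair_table if d > 2.0
        }
        assert pruned_ids == {i + 1 for i in displaced}

    def test_rmsd_pruned_le_rmsd_all(self):
        a, _, _ = make_cyclic_fixture(FixtureSpec(seed=31, noise_sigma=0.5))
        b, _, _ = make_cyclic_fixture(FixtureSpec(seed=32, noise_sigma=0.5))
        res = pruned_match_align(a, b, prune_cutoff=1.0)
        assert res.rmsd_pruned <= res.rmsd_all + 1e-12

    def test_all_pruned_raises(self):
        coords = np.random.default_rng(2).uniform(-20, 20, (10, 3))
        fixed = Assembly("f", ["A"], chain_from_coords(coords))
        moving = Assembly(
            "m", ["A"], chain_from_coords(coords + np.array([50.0, 30.0, 0.0]) * 0 + np.random.default_rng(3).uniform(-20, 20, (10, 3)))
        )
        with pytest.raises(ValueError, match="pruning left"):
            pruned_match_align(moving, fixed, prune_cutoff=0.01)


class TestModuleRotation:
    @pytest.mark.parametrize("angle", [30.0, 90.0, 180.0])
    def test_planted_rotation_recovered_exactly(self, angle):
        s1, s2, dm, truth = make_two_state_fixture(FixtureSpec(seed=5, mobile_rotation=angle))
        tr, diag = module_rotation_angle(s1, s2, dm, ["WHD", "LRR"], ["NB", "HD1"])
        assert tr.angle == pytest.approx(angle, abs=0.1)
        assert diag["anchor_rmsd"] < 1e-9
        assert diag["mobile_internal_rmsd"] < 1e-9

    def test_self_comparison_angle_zero(self, two_state_90):
        s1, _, dm, _ = two_state_90
        tr, _ = module_rotation_angle(s1, s1, dm, ["WHD", "LRR"], ["NB", "HD1"])
        assert tr.angle < 1e-6

    def test_rigidity_check_under_noise(self):
        """Module-internal RMSD stays at noise scale, far below the displacement."""
        s1, s2, dm, _ = make_two_state_fixture(
            FixtureSpec(seed=6, mobile_rotation=90.0, noise_sigma=0.2)
        )
        tr, diag = module_rotation_angle(s1, s2, dm, ["WHD", "LRR"], ["NB", "HD1"])
        assert tr.angle == pytest.approx(90.0, abs=2.0)
        assert diag["mobile_internal_rmsd"] < 1.0

    def test_insufficient_overlap_names_counts(self, two_state_90):
        s1, s2, dm, _ = two_state_90
        # truncate state2 to starve the anchor pairing
        keep = [r for r in s2.residues if r.number <= 65]
        s2_small = Assembly("trunc", ["A"], keep)
        with pytest.raises(ValueError, match="anchor"):
            module_rotation_angle(s1, s2_small, dm, ["WHD", "LRR"], ["NB", "HD1"])

    def test_centroid_angle_utility(self, two_state_90):
        s1, _, dm, _ = two_state_90
        angle = centroid_angle(s1, dm, ("CC", "NB", "HD1"))
        assert 0.0 <= angle <= 180.0
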