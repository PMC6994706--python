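"""Distance maps, the risk-score calibration, and the geometric metrics."""

import numpy as np
import pytest

from callosoplan import (
    LabelVolume,
    RiskModel,
    Trajectory,
    VoxelGrid,
    cc_fraction,
    drilling_angle,
    intracerebral_length,
    min_vessel_distance,
    risk_score,
    sample_nodes,
    vessel_distance_map,
)
from callosoplan.riskmetrics import node_risks


def make_vol(mask, spacing=1.0):
    aff = np.diag([spacing, spacing, spacing, 1.0])
    return LabelVolume(VoxelGrid(mask.shape, aff), mask.astype(np.uint8))


class TestDistanceMap:
    def test_axis_aligned_distance_from_single_vessel_voxel(self):
        mask = np.zeros((16, 16, 16), bool)
        mask[5, 5, 5] = True
        dmap = vessel_distance_map(make_vol(mask))
        assert dmap.values[10, 5, 5] == pytest.approx(5.0)
        assert dmap.values[5, 5, 5] == 0.0

    def test_matches_brute_force_nearest_vessel_search(self):
        rng = np.random.default_rng(11)
        mask = rng.random((32, 32, 32)) < 0.01
        mask[3, 4, 5] = True  # guarantee non-empty
        dmap = vessel_distance_map(make_vol(mask))
        vox = np.argwhere(mask).astype(float)
        grid_pts = np.indices(mask.shape).reshape(3, -1).T.astype(float)
        brute = np.min(np.linalg.norm(
            grid_pts[:, None, :] - vox[None, :, :], axis=2), axis=1)
        assert np.allclose(dmap.values.ravel(), brute)

    def test_spacing_scales_distances(self):
        mask = np.zeros((16, 16, 16), bool)
        mask[5, 5, 5] = True
        dmap = vessel_distance_map(make_vol(mask, spacing=2.0))
        assert dmap.values[10, 5, 5] == pytest.approx(10.0)

    def test_empty_vessel_mask_is_an_error(self):
        with pytest.raises(ValueError):
            vessel_distance_map(make_vol(np.zeros((8, 8, 8), bool)))


class TestSampleNodes:
    def test_two_nodes_are_the_endpoints(self):
        traj = Trajectory([0.0, 0, 0], [10.0, 0, 0])
        nodes = sample_nodes(traj, 2)
        assert np.allclose(nodes, [[0, 0, 0], [10, 0, 0]])

    def test_128_nodes_on_100mm_have_spacing_100_over_127(self):
        traj = Trajectory([0.0, 0, 0], [100.0, 0, 0])
        nodes = sample_nodes(traj, 128)
        gaps = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
        assert np.allclose(gaps, 100 / 127)

    def test_nodes_collinear_with_segment(self):
        traj = Trajectory([1.0, 2, 3], [11.0, -4, 9])
        nodes = sample_nodes(traj, 50)
        rel = nodes - traj.entry
        cross = np.cross(rel, traj.direction)
        assert np.max(np.abs(cross)) < 1e-9

    def test_fewer_than_two_nodes_rejected(self):
        with pytest.raises(ValueError):
            sample_nodes(Trajectory([0.0, 0, 0], [1.0, 0, 0]), 1)


def straight_vessel_volume(offset_axis=1):
    """64³ volume with a straight vessel line of voxels along x at y=z=32."""
    mask = np.zeros((64, 64, 64), bool)
    mask[:, 32, 32] = True
    return make_vol(mask)


class TestRiskScore:
    def test_far_trajectory_scores_zero(self):
        dmap = vessel_distance_map(straight_vessel_volume())
        traj = Trajectory([5.0, 10, 10], [55.0, 10, 10])  # >10 mm clearance
        assert risk_score(traj, dmap) == 0.0

    def test_five_mm_clearance_scores_five_sevenths(self):
        dmap = vessel_distance_map(straight_vessel_volume())
        traj = Trajectory([5.0, 27, 32], [55.0, 27, 32])  # clearance 5 mm
        score = risk_score(traj, dmap)
        assert score == pytest.approx((10 - 5) / 7, abs=1e-6)
        assert score < 1

    def test_one_mm_clearance_matches_node_by_node_oracle(self):
        dmap = vessel_distance_map(straight_vessel_volume())
        traj = Trajectory([5.0, 31, 32], [55.0, 31, 32])  # clearance 1 mm
        model = RiskModel()
        # independent per-node evaluation from the piecewise definition
        d = dmap.sample(sample_nodes(traj, model.n_nodes))
        expected = max(
            0 if di >= 10 else (10 - di) / 7 if di >= 3 else 1 + (3 - di) / 3
            for di in d)
        score = risk_score(traj, dmap, model)
        assert score == pytest.approx(expected, abs=1e-12)
        assert score == pytest.approx(1 + 2 / 3, abs=0.05)

    def test_mean_aggregation_never_exceeds_max(self):
        dmap = vessel_distance_map(straight_vessel_volume())
        traj = Trajectory([5.0, 28, 35], [55.0, 36, 29])
        mx = risk_score(traj, dmap, RiskModel(aggregation="max"))
        mn = risk_score(traj, dmap, RiskModel(aggregation="mean"))
        assert mn <= mx

    def test_node_outside_grid_is_an_error(self):
        dmap = vessel_distance_map(straight_vessel_volume())
        with pytest.raises(ValueError):
            risk_score(Trajectory([5.0, 5, 5], [200.0, 5, 5]), dmap)

    def test_calibration_score_below_one_iff_clearance_above_three(self):
        """The central calibration, randomized: score < 1 ⟺ every node more
        than 3 mm from vasculature, with zero counterexamples."""
        rng = np.random.default_rng(99)
        n_checked = 0
        for _ in range(25):
            mask = rng.random((24, 24, 24)) < 0.004
            mask[rng.integers(24), rng.integers(24), rng.integers(24)] = True
            dmap = vessel_distance_map(make_vol(mask))
            for _ in range(20):
                a = rng.uniform(2, 21, 3)
                b = rng.uniform(2, 21, 3)
                if np.linalg.norm(b - a) < 1.0:
                    continue
                traj = Trajectory(a, b)
                score = risk_score(traj, dmap)
                mind = min_vessel_distance(traj, dmap)
                assert (score < 1) == (mind > 3.0), (score, mind)
                n_checked += 1
        assert n_checked >= 400

    def test_risk_antimonotone_in_vessel_removal(self):
        """Dilating free space (removing vessel voxels) never raises risk."""
        rng = np.random.default_rng(5)
        mask = rng.random((32, 32, 32)) < 0.01
        mask[10, 10, 10] = True
        smaller = mask.copy()
        smaller[mask] = rng.random(mask.sum()) < 0.5
        smaller[10, 10, 10] = True
        traj = Trajectory([3.0, 3, 3], [28.0, 28, 28])
        d_all = vessel_distance_map(make_vol(mask))
        d_few = vessel_distance_map(make_vol(smaller))
        assert risk_score(traj, d_few) <= risk_score(traj, d_all)
        assert (min_vessel_distance(traj, d_few)
                >= min_vessel_distance(traj, d_all))


class TestMinVesselDistance:
    def test_zero_along_the_vessel(self):
        dmap = vessel_distance_map(straight_vessel_volume())
        traj = Trajectory([5.0, 32, 32], [55.0, 32, 32])  # collinear with vessel
        assert min_vessel_distance(traj, dmap) == pytest.approx(0.0, abs=1e-9)

    def test_transverse_crossing_is_within_node_spacing_of_zero(self):
        dmap = vessel_distance_map(straight_vessel_volume())
        traj = Trajectory([32.0, 32, 5], [32.0, 32, 60])
        assert min_vessel_distance(traj, dmap) < 0.5

    def test_parallel_tube_clearance_recovered(self):
        dmap = vessel_distance_map(straight_vessel_volume())
        traj = Trajectory([5.0, 28, 32], [55.0, 28, 32])  # 4 mm clearance
        assert min_vessel_distance(traj, dmap) == pytest.approx(4.0, abs=0.5)

    def test_min_bounds_every_node(self):
        dmap = vessel_distance_map(straight_vessel_volume())
        traj = Trajectory([5.0, 20, 40], [55.0, 40, 20])
        d = dmap.sample(sample_nodes(traj, 128))
        assert min_vessel_distance(traj, dmap) <= d.min() + 1e-12


class TestIntracerebralLength:
    def _slab_brain(self):
        mask = np.zeros((96, 96, 96), bool)
        mask[:, :, :70] = True  # brain fills z < 70
        return make_vol(mask)

    def test_constructed_depth_recovered(self):
        brain = self._slab_brain()
        traj = Trajectory([48.0, 48, 90], [48.0, 48, 10])  # enters at z=69.x
        icl = intracerebral_length(traj, brain)
        assert icl == pytest.approx(60.0, abs=1.0)

    def test_target_outside_brain_is_an_error(self):
        brain = self._slab_brain()
        with pytest.raises(ValueError):
            intracerebral_length(Trajectory([48.0, 48, 90], [48.0, 48, 75]),
                                 brain)

    def test_shrinking_brain_cannot_lengthen(self):
        brain = self._slab_brain()
        smaller = np.zeros((96, 96, 96), bool)
        smaller[:, :, :60] = True
        traj = Trajectory([48.0, 48, 90], [48.0, 48, 10])
        assert (intracerebral_length(traj, make_vol(smaller))
                <= intracerebral_length(traj, brain))


class TestDrillingAngle:
    def _slab_skull(self):
        mask = np.zeros((64, 64, 64), bool)
        mask[:, :, :30] = True  # flat surface at z=29.5
        return make_vol(mask)

    def test_normal_incidence_on_flat_slab(self):
        skull = self._slab_skull()
        traj = Trajectory([32.0, 32, 29.5], [32.0, 32, 5])
        assert drilling_angle(traj, skull) == pytest.approx(0.0, abs=2.0)

    def test_45_degree_incidence(self):
        skull = self._slab_skull()
        traj = Trajectory([32.0, 32, 29.5], [32.0 + 17, 32, 29.5 - 17])
        assert drilling_angle(traj, skull) == pytest.approx(45.0, abs=3.0)

    def test_unsigned_under_direction_flip(self):
        skull = self._slab_skull()
        a = drilling_angle(Trajectory([32.0, 32, 29.5], [40.0, 32, 10]), skull)
        # same entry, exactly negated direction → identical unsigned angle
        c = drilling_angle(Trajectory([32.0, 32, 29.5], [24.0, 32, 49]), skull)
        assert a == pytest.approx(c, abs=1e-6)

    def test_entry_far_from_surface_is_an_error(self):
        skull = self._slab_skull()
        with pytest.raises(ValueError):
            drilling_angle(Trajectory([32.0, 32, 45], [32.0, 32, 5]), skull)


class TestCcFraction:
    def _slab_cc(self):
        mask = np.zeros((64, 64, 64), bool)
        mask[:, :, 20:40] = True
        return make_vol(mask)

    def test_fully_inside_is_one(self):
        cc = self._slab_cc()
        traj = Trajectory([32.0, 32, 38], [32.0, 32, 22])
        assert cc_fraction(traj, cc, 10.0) == 1.0

    def test_fully_outside_is_zero(self):
        cc = self._slab_cc()
        traj = Trajectory([32.0, 32, 60], [32.0, 32, 45])
        assert cc_fraction(traj, cc, 10.0) == 0.0

    def test_half_in_across_flat_boundary(self):
        cc = self._slab_cc()
        traj = Trajectory([32.0, 32, 60], [32.0, 32, 29.5])  # 10 mm in, 10 out
        assert cc_fraction(traj, cc, 20.0) == pytest.approx(0.5, abs=0.05)
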