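"""Dose-volume statistics, HI, trajectories and micro-CT segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holoperf import (
    DomainError,
    MicroCTParams,
    VolumeGrid,
    dose_percentile,
    hi_trajectory,
    homogeneity_index,
    segment_microct,
)

from tests._oracles import brute_force_dp


class TestDosePercentile:
    def test_uniform_map(self):
        vals = np.full(200, 10.0)
        assert dose_percentile(vals, 2.0) == 10.0
        assert dose_percentile(vals, 98.0) == 10.0

    def test_hundred_voxel_oracle(self):
        doses = np.arange(1.0, 101.0)  # 1..100 Gy
        assert dose_percentile(doses, 2.0) == pytest.approx(98.02)
        assert brute_force_dp(doses, 2.0) == pytest.approx(98.02)

    def test_percentile_monotone_in_p(self):
        rng = np.random.default_rng(0)
        doses = rng.gamma(2.0, 10.0, size=5000)
        d2 = dose_percentile(doses, 2.0)
        d50 = dose_percentile(doses, 50.0)
        d98 = dose_percentile(doses, 98.0)
        assert d2 >= d50 >= d98

    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.floats(min_value=1.0, max_value=99.0))
    @settings(deadline=None, max_examples=40)
    def test_agrees_with_brute_force_oracle(self, seed, p):
        rng = np.random.default_rng(seed)
        doses = rng.exponential(30.0, size=rng.integers(10, 10_000))
        assert dose_percentile(doses, p) == pytest.approx(
            brute_force_dp(doses, p), rel=1e-12
        )

    def test_empty_mask_rejected(self):
        grid = VolumeGrid(np.ones((3, 3, 3)), mask=np.zeros((3, 3, 3), bool))
        with pytest.raises(DomainError, match="empty mask"):
            dose_percentile(grid, 2.0)


class TestHomogeneityIndex:
    def test_uniform_map_zero(self):
        stats = homogeneity_index(np.full(1000, 42.0))
        assert stats.hi == 0.0

    def test_two_level_map(self):
        # half 10 Gy, half 30 Gy: D2=30, D98=10, Dmean=20 -> HI = 1.0
        doses = np.concatenate([np.full(500, 10.0), np.full(500, 30.0)])
        stats = homogeneity_index(doses)
        assert stats.d2 == pytest.approx(30.0)
        assert stats.d98 == pytest.approx(10.0)
        assert stats.dmean == pytest.approx(20.0)
        assert stats.hi == pytest.approx(1.0)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(deadline=None, max_examples=25)
    def test_scale_invariance(self, alpha):
        rng = np.random.default_rng(5)
        doses = rng.gamma(2.0, 5.0, size=2000)
        assert homogeneity_index(alpha * doses).hi == pytest.approx(
            homogeneity_index(doses).hi, rel=1e-9
        )

    def test_zero_mean_flagged_nan(self):
        stats = homogeneity_index(np.zeros(100))
        assert np.isnan(stats.hi)

    def test_whole_liver_at_least_as_heterogeneous_as_hot_lobe(
        self, labels_small, trees_small, schedule_small
    ):
        # cold lobes inflate the whole-organ HI above the best-dosed lobe's
        from holoperf.phantom import FlowCondition, simulate_deposition

        truth = simulate_deposition(
            labels_small, trees_small, schedule_small,
            FlowCondition.from_name("low"), seed=2,
        )
        conc = truth.true_concentration[-1].values
        whole = homogeneity_index(conc, mask=labels_small.liver_mask).hi
        hot_lobe = 1 + int(np.argmax(truth.lobe_mass_mg() / labels_small.lobe_volumes_ml()))
        lobe_hi = homogeneity_index(conc, mask=labels_small.labels == hot_lobe).hi
        assert whole >= lobe_hi


class TestHiTrajectory:
    def test_loading_axis(self):
        maps = [VolumeGrid(np.full((4, 4, 4), v)) for v in (1.0, 2.0, 3.0, 4.0, 5.0)]
        df = hi_trajectory(maps, [250, 500, 750, 1000, 1250], 1250.0)
        np.testing.assert_allclose(df.mg_per_ml, [0.2, 0.4, 0.6, 0.8, 1.0])

    def test_single_map_rejected(self):
        with pytest.raises(DomainError, match=">= 2"):
            hi_trajectory([VolumeGrid(np.ones((2, 2, 2)))], [100], 100.0)

    def test_inconsistent_geometry_rejected(self):
        maps = [VolumeGrid(np.ones((2, 2, 2))), VolumeGrid(np.ones((3, 3, 3)))]
        with pytest.raises(DomainError, match="geometry"):
            hi_trajectory(maps, [1, 2], 10.0)


class TestSegmentMicroCT:
    def test_exact_threshold_mask(self):
        rng = np.random.default_rng(1)
        vals = rng.choice([0.0, 500.0], size=(12, 12, 12))
        grid = VolumeGrid(vals, spacing=0.03)
        mask, _ = segment_microct(grid, MicroCTParams())
        np.testing.assert_array_equal(mask, vals == 500.0)

    def test_cylinder_radius_estimate(self):
        # cylinder of radius 0.09 mm at 0.03 mm voxels
        n, spacing, radius = 40, 0.03, 0.09
        ax = (np.arange(n) - n / 2) * spacing
        x, y, _ = np.meshgrid(ax, ax, ax, indexing="ij")
        vals = np.where(np.hypot(x, y) <= radius, 800.0, 40.0)
        grid = VolumeGrid(vals, spacing=spacing)
        _, table = segment_microct(grid, MicroCTParams())
        assert len(table) == 1
        assert table.radius_mm.iloc[0] == pytest.approx(radius, abs=0.03)

    def test_threshold_above_max_empty_table(self):
        grid = VolumeGrid(np.full((6, 6, 6), 100.0), spacing=0.03)
        mask, table = segment_microct(grid, MicroCTParams(threshold_hu=350.0))
        assert not mask.any()
        assert table.empty

    def test_component_count_26_connectivity(self):
        vals = np.zeros((10, 10, 10))
        vals[1, 1, 1] = 500.0
        vals[2, 2, 2] = 500.0  # diagonal touch: one component at 26-conn
        vals[7, 7, 7] = 500.0
        grid = VolumeGrid(vals, spacing=0.03)
        _, t26 = segment_microct(grid, MicroCTParams(connectivity=26))
        _, t6 = segment_microct(grid, MicroCTParams(connectivity=6))
        assert len(t26) == 2
        assert len(t6) == 3
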