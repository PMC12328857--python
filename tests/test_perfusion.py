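"""DCE time-intensity curves, percent enhancement and wash-in slopes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holoperf import DomainError, DynamicSeries
from holoperf.perfusion import (
    TimeIntensityCurve,
    analyze_dce,
    extract_tic,
    max_washin_slope,
    percent_enhancement,
    relative_perfusion,
)
from holoperf.phantom import DceParams, synthesize_dce


def _tic(s_t, s0=100.0, dt=1.0):
    s_t = np.asarray(s_t, float)
    return TimeIntensityCurve(lobe=1, s0_lobe=s0, s_t=s_t,
                              times_s=dt * np.arange(s_t.size))


class TestPercentEnhancement:
    def test_post_injection_denominator_convention(self):
        # the pinned convention: PE = 100 (S1 - S0) / S1
        pe = percent_enhancement(_tic([200.0]))
        assert pe[0] == pytest.approx(50.0)

    def test_no_enhancement_zero(self):
        pe = percent_enhancement(_tic([100.0]))
        assert pe[0] == pytest.approx(0.0)

    def test_regression_pin_against_conventional_form(self):
        # s0=100, s=400: printed convention gives 75; conventional gives 300
        tic = _tic([400.0])
        assert percent_enhancement(tic)[0] == pytest.approx(75.0)
        assert percent_enhancement(tic, conventional=True)[0] == pytest.approx(300.0)

    def test_nonpositive_signal_undefined(self):
        pe = percent_enhancement(_tic([0.0, -5.0, 200.0]))
        assert np.isnan(pe[0]) and np.isnan(pe[1])
        assert pe[2] == pytest.approx(50.0)

    @given(st.floats(min_value=0.1, max_value=100.0))
    @settings(deadline=None, max_examples=25)
    def test_invariant_under_global_scaling(self, alpha):
        s_t = np.array([110.0, 150.0, 230.0])
        base = percent_enhancement(_tic(s_t, s0=100.0))
        scaled = percent_enhancement(_tic(alpha * s_t, s0=alpha * 100.0))
        np.testing.assert_allclose(scaled, base, rtol=1e-9)


class TestMaxWashinSlope:
    def test_linear_ramp_exact(self):
        t = np.arange(40, dtype=float)
        pe = 2.0 * t  # %/s with dt = 1 s
        slope, _, flagged = max_washin_slope(pe, 1.0)
        assert not flagged
        assert slope == pytest.approx(2.0, rel=1e-9)

    def test_smooth_washin_close_to_analytic(self):
        from holoperf.phantom.imaging import washin_shape

        dt, t0, rise, amp = 0.86, 30.0, 45.0, 60.0
        t = dt * np.arange(200)
        pe = amp * washin_shape((t - t0) / rise)
        slope, _, _ = max_washin_slope(pe, dt)
        analytic = amp * (15 / 8) / rise
        assert slope == pytest.approx(analytic, rel=0.05)

    def test_flat_curve_flagged_non_enhancing(self):
        rng = np.random.default_rng(0)
        pe = rng.normal(0.0, 0.2, size=100)
        slope, _, flagged = max_washin_slope(pe, 0.86, noise_threshold=1.0)
        assert flagged and slope == 0.0

    def test_time_rescaling_equivariance(self):
        pe = np.concatenate([np.zeros(10), np.linspace(0, 50, 30), np.full(20, 50.0)])
        s1, _, _ = max_washin_slope(pe, 1.0)
        s2, _, _ = max_washin_slope(pe, 0.5)
        assert s2 == pytest.approx(2 * s1, rel=1e-9)


class TestRelativePerfusion:
    def test_equal_slopes(self):
        np.testing.assert_allclose(relative_perfusion(np.ones(5)), 0.2)

    def test_proportional_shares(self):
        shares = relative_perfusion(np.array([2.0, 1.0, 1.0, 0.0, 0.0]))
        np.testing.assert_allclose(shares, [0.5, 0.25, 0.25, 0.0, 0.0])

    def test_all_zero_rejected(self):
        with pytest.raises(DomainError):
            relative_perfusion(np.zeros(5))


class TestExtractTic:
    def test_constant_series(self, labels_small):
        data = np.full(labels_small.shape + (30,), 123.0)
        series = DynamicSeries.from_array(data, 0.86, spacing=labels_small.spacing)
        for tic in extract_tic(series, labels_small, baseline_frames=5):
            assert tic.s0_lobe == pytest.approx(123.0)
            np.testing.assert_allclose(tic.s_t, 123.0)

    def test_baseline_frames_validated(self, labels_small):
        data = np.zeros(labels_small.shape + (10,))
        series = DynamicSeries.from_array(data, 0.86, spacing=labels_small.spacing)
        with pytest.raises(DomainError, match="baseline_frames"):
            extract_tic(series, labels_small, baseline_frames=10)

    def test_empty_lobe_reported_by_name(self, labels_small):
        import dataclasses

        labels = dataclasses.replace(labels_small)
        # bypass construction check to simulate a mismatched ROI set
        labels.labels = labels_small.labels.copy()
        labels.labels[labels.labels == 5] = 0
        data = np.zeros(labels.shape + (20,))
        series = DynamicSeries.from_array(data, 0.86, spacing=labels.spacing)
        with pytest.raises(DomainError, match="caudate"):
            extract_tic(series, labels, baseline_frames=5)


class TestGeneratorRecovery:
    def test_noiseless_recovery_of_perfusion_shares(self, labels_small,
                                                    perfusion_uneven):
        series = synthesize_dce(labels_small, perfusion_uneven, DceParams())
        result = analyze_dce(series, labels_small)
        np.testing.assert_allclose(
            result.relative_perfusion, perfusion_uneven, atol=1e-3
        )
        assert not result.non_enhancing.any()

    def test_recovery_under_noise(self, labels_small, perfusion_uneven):
        # noise SD = 2% of S0; lobe averaging leaves shares within 0.02
        errs = []
        for seed in range(10):
            series = synthesize_dce(
                labels_small, perfusion_uneven,
                DceParams(noise_sd=10.0), seed=seed,
            )
            result = analyze_dce(series, labels_small)
            errs.append(np.abs(result.relative_perfusion - perfusion_uneven).max())
        assert np.mean(errs) < 0.02

    def test_lobe_curve_matches_generator(self, labels_small):
        from holoperf.phantom.imaging import washin_shape

        p = np.full(5, 0.2)
        params = DceParams()
        series = synthesize_dce(labels_small, p, params)
        tic = extract_tic(series, labels_small)[2]
        t = tic.times_s
        expected_pe = params.pe_max_percent * washin_shape((t - params.t0_s) / params.rise_s)
        expected_s = params.s0 / (1 - expected_pe / 100.0)
        np.testing.assert_allclose(tic.s_t, expected_s, rtol=1e-9)
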