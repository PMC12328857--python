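"""R2* fitting, concentration mapping and fictive dose computation."""

import numpy as np
import pytest

from holoperf import (
    DosimetryConstants,
    FormatError,
    MultiEchoSeries,
    VolumeGrid,
    concentration_for_dose,
    concentration_map,
    default_echo_times,
    dose_map,
    fit_r2star,
    lobe_dose_summary,
)
from holoperf.dosimetry import DoseMap
from holoperf.phantom import MultiEchoParams, synthesize_multiecho
from tests._oracles import decay_series as _series


class TestFitR2Star:
    def test_noiseless_fit_exact(self):
        rmap = fit_r2star(_series(100.0))
        np.testing.assert_allclose(rmap.r2star.values, 100.0, rtol=1e-9)
        np.testing.assert_allclose(rmap.s0.values, 1000.0, rtol=1e-9)
        assert rmap.valid.all()

    def test_rician_bias_small_at_snr_50(self):
        # 500 voxels at R2* = 100 /s, noise such that SNR at TE1 is 50
        s0 = 1000.0
        noise_sd = s0 * np.exp(-100 * 1.7e-3) / 50.0
        series = _series(100.0, noise_sd=noise_sd, shape=(25, 20, 1), seed=7)
        rmap = fit_r2star(series, noise_floor=3 * noise_sd)
        est = rmap.r2star.values[rmap.valid]
        assert est.size == 500
        mean_abs_rel_bias = abs(est.mean() - 100.0) / 100.0
        assert mean_abs_rel_bias < 0.02

    def test_all_echoes_below_floor_invalid_not_zero(self):
        series = _series(100.0, s0=1.0)
        rmap = fit_r2star(series, noise_floor=10.0)
        assert not rmap.valid.any()
        assert np.isnan(rmap.r2star.values).all()

    def test_fewer_than_three_echoes_rejected(self):
        with pytest.raises(FormatError, match="3 echoes"):
            fit_r2star(_series(50.0, n_echoes=2))

    def test_clipped_to_r2star_max(self):
        rmap = fit_r2star(_series(100.0), r2star_max_s=50.0)
        assert np.nanmax(rmap.r2star.values) <= 50.0


class TestConcentrationMap:
    def test_unit_delta(self):
        post = fit_r2star(_series(125.0))
        base = fit_r2star(_series(35.0))
        conc, qc = concentration_map(post, base)  # r2* default 90
        np.testing.assert_allclose(conc.values, 1.0, rtol=1e-9)
        assert qc["negative_delta_voxels"] == 0

    def test_negative_delta_clamped_and_counted(self):
        post = fit_r2star(_series(30.0))
        base = fit_r2star(_series(35.0))
        conc, qc = concentration_map(post, base)
        np.testing.assert_allclose(conc.values, 0.0, atol=1e-12)
        assert qc["negative_delta_voxels"] == conc.values.size

    def test_scalar_baseline(self):
        post = fit_r2star(_series(125.0))
        conc, _ = concentration_map(post, 35.0)
        np.testing.assert_allclose(conc.values, 1.0, rtol=1e-9)

    def test_geometry_mismatch_rejected(self):
        post = fit_r2star(_series(100.0, shape=(5, 5, 4)))
        base = fit_r2star(_series(35.0, shape=(4, 4, 4)))
        with pytest.raises(FormatError, match="geometry"):
            concentration_map(post, base)

    def test_phantom_roundtrip_noiseless(self, truth_medium, labels_small):
        conc_true = truth_medium.true_concentration[-1]
        params = MultiEchoParams()
        base = fit_r2star(
            synthesize_multiecho(conc_true.with_values(np.zeros(conc_true.shape)), params)
        )
        post = fit_r2star(synthesize_multiecho(conc_true, params))
        conc, _ = concentration_map(post, base)
        liver = labels_small.liver_mask
        err = np.abs(conc.values[liver] - conc_true.values[liver])
        assert np.nanmax(err) < 1e-6

    def test_misspecified_relaxivity_biases_linearly(self):
        post = fit_r2star(_series(125.0))
        base = fit_r2star(_series(35.0))
        conc_biased, _ = concentration_map(
            post, base, DosimetryConstants(relaxivity_s_per_mg_ml=45.0)
        )
        np.testing.assert_allclose(conc_biased.values, 2.0, rtol=1e-9)


class TestDoseLaw:
    def test_dose_limit_conversions_2dp(self):
        assert round(concentration_for_dose(60.0), 2) == 0.33
        assert round(concentration_for_dose(300.0), 2) == 1.64

    def test_dose_from_concentration_inverse_of_limit(self):
        c = concentration_for_dose(60.0)
        grid = VolumeGrid(np.full((3, 3, 3), c), spacing=2.0)
        dm = dose_map(grid)
        np.testing.assert_allclose(dm.dose.values, 60.0, rtol=1e-3)

    def test_zero_concentration_zero_dose(self):
        dm = dose_map(VolumeGrid(np.zeros((3, 3, 3)), spacing=2.0))
        assert np.all(dm.dose.values == 0)

    def test_doubling_specific_activity_doubles_dose(self):
        grid = VolumeGrid(np.full((2, 2, 2), 0.5), spacing=2.0)
        d1 = dose_map(grid, DosimetryConstants())
        d2 = dose_map(grid, DosimetryConstants(specific_activity_mbq_mg=24.0))
        np.testing.assert_allclose(d2.dose.values, 2 * d1.dose.values, rtol=1e-12)

    def test_inverse_property(self):
        const = DosimetryConstants()
        for c in (0.1, 1.0, 3.7):
            grid = VolumeGrid(np.full((2, 2, 2), c), spacing=1.0)
            d = dose_map(grid, const).dose.values[0, 0, 0]
            assert concentration_for_dose(d, const) == pytest.approx(c, rel=1e-12)

    def test_whole_liver_dose_at_study_loading(self):
        # internal consistency of constants: 1.45 mg/mL ~ 265 Gy
        d = DosimetryConstants().gy_per_mg_ml * 1.45
        assert d == pytest.approx(265.0, rel=0.02)


class TestLobeDoseSummary:
    def test_uniform_map(self, labels_small):
        dm = DoseMap(dose=VolumeGrid(np.full(labels_small.shape, 10.0),
                                     spacing=labels_small.spacing))
        table = lobe_dose_summary(dm, labels_small)
        np.testing.assert_allclose(table.mean_dose_gy, 10.0)
        np.testing.assert_allclose(table.d2_gy, 10.0)
        np.testing.assert_allclose(table.d98_gy, 10.0)

    def test_partition_additivity(self, labels_small):
        rng = np.random.default_rng(3)
        dose = rng.random(labels_small.shape) * labels_small.liver_mask
        dm = DoseMap(dose=VolumeGrid(dose, spacing=labels_small.spacing))
        table = lobe_dose_summary(dm, labels_small)
        total = (table.mean_dose_gy * table.volume_ml).sum()
        liver = labels_small.liver_mask
        whole = dose[liver].mean() * liver.sum() * labels_small.voxel_volume_ml
        assert total == pytest.approx(whole, rel=1e-9)

    def test_lobe_mass_accounting(self, truth_medium, labels_small):
        # noiseless truth: lobe mean dose equals the mass-accounting value
        const = DosimetryConstants()
        dm = dose_map(truth_medium.true_concentration[-1], const)
        table = lobe_dose_summary(dm, labels_small)
        analytic = (
            const.gy_per_mg_ml
            * truth_medium.lobe_mass_mg()
            / labels_small.lobe_volumes_ml()
        )
        np.testing.assert_allclose(table.mean_dose_gy, analytic, rtol=0.02)

    def test_end_to_end_linearity_in_mass(self, truth_medium):
        conc = truth_medium.true_concentration[-1]
        d1 = dose_map(conc).dose.values
        d2 = dose_map(conc.with_values(3.0 * conc.values)).dose.values
        np.testing.assert_allclose(d2, 3.0 * d1, rtol=1e-12)
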