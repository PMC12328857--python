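"""Microsphere transport and deposition."""

import numpy as np
import pytest

from holoperf.phantom import (
    FlowCondition,
    FractionSchedule,
    MicrosphereSpec,
    simulate_deposition,
)


class TestFlowCondition:
    def test_pv_is_three_times_ha(self):
        for name, ha in (("low", 0.02), ("medium", 0.15), ("high", 0.22)):
            cond = FlowCondition.from_name(name)
            assert cond.ha_flow_per_gram == ha
            assert cond.pv_flow_per_gram == pytest.approx(3 * ha)

    def test_mixing_increases_with_flow(self):
        mix = [FlowCondition.from_name(n).mixing for n in ("low", "medium", "high")]
        assert mix[0] < mix[1] < mix[2]

    def test_mixing_bounds(self):
        with pytest.raises(ValueError):
            FlowCondition("x", 0.1, 1.5)


class TestSchedule:
    def test_delivered_mass_with_residual(self):
        sched = FractionSchedule((100.0, 200.0), residual_fraction=0.1)
        assert sched.total_delivered_mg == pytest.approx(270.0)

    def test_extended_schedule(self):
        sched = FractionSchedule.extended()
        assert sched.n_fractions == 9
        assert sched.total_delivered_mg == pytest.approx(5 * 250 + 4 * 1000)

    def test_positive_masses_required(self):
        with pytest.raises(ValueError):
            FractionSchedule((0.0,))


class TestMicrosphereSpec:
    def test_sphere_mass_from_geometry(self):
        spec = MicrosphereSpec()  # 30 um, 1.4 g/mL
        # hand formula: m = rho * pi d^3 / 6
        d_cm = 30e-4
        mass_mg = 1.4 * np.pi / 6 * d_cm**3 * 1e3
        assert spec.mass_per_sphere_mg == pytest.approx(mass_mg)
        assert spec.spheres_per_mg == pytest.approx(5.05e4, rel=5e-3)


class TestDeposition:
    def test_mass_conservation_exact(self, labels_small, trees_small, schedule_small):
        for seed in range(3):
            for cond in ("low", "high"):
                truth = simulate_deposition(
                    labels_small, trees_small, schedule_small,
                    FlowCondition.from_name(cond), seed=seed, rasterise=False,
                )
                assert truth.total_deposited_mg() == pytest.approx(
                    schedule_small.total_delivered_mg, rel=1e-12
                )

    def test_full_mixing_recovers_lobe_flow(self, labels_small, trees_small,
                                            schedule_small, perfusion_uneven):
        # mixing = 1, no lodging: per-lobe mass shares equal lobe flow
        # fractions within binomial error over n packets
        truth = simulate_deposition(
            labels_small, trees_small, schedule_small,
            FlowCondition("ideal", 0.22, 1.0),
            seed=0, lobe_perfusion=perfusion_uneven, lam=0.0, rasterise=False,
        )
        shares = truth.lobe_mass_mg() / truth.total_deposited_mg()
        n = 5 * 10_000
        sd = np.sqrt(perfusion_uneven * (1 - perfusion_uneven) / n)
        assert np.all(np.abs(shares - perfusion_uneven) < 5 * sd)

    def test_low_flow_lodges_proximally(self, labels_small, trees_small,
                                        schedule_small):
        low = simulate_deposition(
            labels_small, trees_small, schedule_small,
            FlowCondition.from_name("low"), seed=4, rasterise=False,
        )
        high = simulate_deposition(
            labels_small, trees_small, schedule_small,
            FlowCondition.from_name("high"), seed=4, rasterise=False,
        )
        assert low.mass_fraction_in_generations(3) > high.mass_fraction_in_generations(3)

    def test_mean_lodged_generation_increases_with_mixing(
        self, labels_small, trees_small, schedule_small
    ):
        gens = []
        for mixing in (0.1, 0.5, 0.9):
            vals = [
                simulate_deposition(
                    labels_small, trees_small, schedule_small,
                    FlowCondition("c", 0.1, mixing), seed=s, rasterise=False,
                ).mean_lodged_generation()
                for s in range(5)
            ]
            gens.append(np.mean(vals))
        assert gens[0] < gens[1] < gens[2]

    def test_concentration_nonnegative_and_mass_consistent(self, truth_medium):
        for conc in truth_medium.true_concentration:
            assert np.all(conc.values >= 0)
        final = truth_medium.true_concentration[-1]
        grid_mass = final.values.sum() * final.voxel_volume_ml
        assert grid_mass == pytest.approx(truth_medium.total_deposited_mg(), rel=1e-9)

    def test_lobe_mass_matches_rasterised_map(self, truth_medium, labels_small):
        conc = truth_medium.true_concentration[-1]
        vox_ml = labels_small.voxel_volume_ml
        raster = np.array(
            [conc.values[labels_small.labels == l].sum() * vox_ml for l in range(1, 6)]
        )
        np.testing.assert_allclose(raster, truth_medium.lobe_mass_mg(), rtol=1e-9)

    def test_hi_calibration_bands(self, labels_small, trees_small, schedule_small):
        # qualitative calibration: low-flow administrations land in the
        # heterogeneous band, high-flow in the homogeneous band, with the
        # medium condition in between
        from holoperf.metrics import homogeneity_index

        means = {}
        for cond in ("low", "medium", "high"):
            vals = [
                homogeneity_index(
                    simulate_deposition(
                        labels_small, trees_small, schedule_small,
                        FlowCondition.from_name(cond), seed=s,
                    ).true_concentration[-1].values,
                    mask=labels_small.liver_mask,
                ).hi
                for s in range(6)
            ]
            means[cond] = float(np.mean(vals))
        assert 3.5 <= means["low"] <= 5.0
        assert 1.5 <= means["high"] <= 2.5
        assert means["low"] > means["medium"] > means["high"]

    def test_trees_must_cover_all_lobes(self, labels_small, trees_small,
                                        schedule_small):
        partial = {k: v for k, v in trees_small.items() if k != 5}
        with pytest.raises(ValueError, match="5 lobes"):
            simulate_deposition(
                labels_small, partial, schedule_small,
                FlowCondition.from_name("low"), seed=0,
            )
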