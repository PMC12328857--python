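"""End-to-end pipeline: simulate -> r2star -> dose -> dce -> metrics -> associate.

``run_pipeline`` executes the full chain from a validated config, writes
volumes (NIfTI), tables (CSV) and a summary (JSON), and returns the
summary dict.  The run is a pure function of (config, seed): repeated runs
produce byte-identical summaries.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .association import correlate_perfusion_deposition, microsphere_counts
from .config import PipelineConfig
from .dosimetry import (
    DosimetryConstants,
    concentration_map,
    dose_map,
    fit_r2star,
    lobe_dose_summary,
)
from .grids import default_echo_times
from .metrics import hi_trajectory, homogeneity_index
from .perfusion import analyze_dce
from .phantom import (
    DceParams,
    FlowCondition,
    FractionSchedule,
    MicrosphereSpec,
    MultiEchoParams,
    build_liver_phantom,
    grow_arterial_tree,
    lobe_perfusion_fractions,
    simulate_deposition,
    synthesize_dce,
    synthesize_multiecho,
)
from .seeding import substream_seed

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("holoperf")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


def _round_floats(obj, ndigits: int = 10):
    """Round floats recursively so summaries are stable across platforms."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: PipelineConfig, outdir=None, write_volumes: bool = True) -> dict:
    """Run the full phantom-to-report chain.

    Parameters
    ----------
    config : PipelineConfig
    outdir : path, optional
        Output directory; nothing is written when None.
    write_volumes : bool
        Also write the (large) NIfTI volumes, not just tables and summary.
    """
    seed = config.seed
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    condition = FlowCondition.from_name(
        config.condition.name, mixing=config.condition.mixing
    )
    log.info(
        "condition %s: HA flow %.3f mL/min/g, PV flow %.3f mL/min/g "
        "(PV = 3 x HA), mixing %.2f",
        condition.name,
        condition.ha_flow_per_gram,
        condition.pv_flow_per_gram,
        condition.mixing,
    )

    # --- simulate ---------------------------------------------------------
    @_stage("simulate")
    def simulate():
        labels = build_liver_phantom(
            shape=config.grid.shape,
            spacing=config.grid.spacing_mm,
            volume_fractions=config.phantom.volume_fractions,
            target_volume_ml=config.phantom.target_volume_ml,
            seed=seed,
        )
        trees = {
            lobe: grow_arterial_tree(
                labels.lobe_mask(lobe),
                labels.spacing,
                generations=config.phantom.tree_generations,
                seed=substream_seed(seed, f"tree-{lobe}"),
                root_radius_mm=config.phantom.root_radius_mm,
            )
            for lobe in range(1, 6)
        }
        perfusion = lobe_perfusion_fractions(
            labels,
            seed=seed,
            jitter=config.phantom.perfusion_jitter,
            override=config.phantom.perfusion_override,
        )
        schedule = FractionSchedule(
            masses_mg=config.schedule.masses_mg,
            residual_fraction=config.schedule.residual_fraction,
        )
        spheres = MicrosphereSpec(
            diameter_um=config.spheres.diameter_um,
            density_g_ml=config.spheres.density_g_ml,
        )
        truth = simulate_deposition(
            labels,
            trees,
            schedule,
            condition,
            spheres=spheres,
            seed=seed,
            lobe_perfusion=perfusion,
            n_packets_per_fraction=config.deposition.n_packets_per_fraction,
            gamma=config.deposition.gamma,
            lam=config.deposition.lam,
            tau_g=config.deposition.tau_g,
            blur_sigma_vox=config.deposition.blur_sigma_vox,
        )
        return labels, truth

    labels, truth = simulate()
    constants = DosimetryConstants(
        specific_activity_mbq_mg=config.dosimetry.specific_activity_mbq_mg,
        relaxivity_s_per_mg_ml=config.dosimetry.relaxivity_s_per_mg_ml,
        dose_factor_gy_kg_gbq=config.dosimetry.dose_factor_gy_kg_gbq,
        tissue_density_g_ml=config.dosimetry.tissue_density_g_ml,
    )

    # --- r2star + dose per cumulative fraction ---------------------------
    me_params = MultiEchoParams(
        echo_times_ms=tuple(
            default_echo_times(
                config.multiecho.n_echoes,
                config.multiecho.te1_ms,
                config.multiecho.delta_te_ms,
            )
        ),
        s0=config.multiecho.s0,
        r2star_baseline_s=config.multiecho.r2star_baseline_s,
        relaxivity_s_per_mg_ml=constants.relaxivity_s_per_mg_ml,
    )

    @_stage("r2star")
    def fit_baseline():
        zero = truth.true_concentration[0].with_values(
            np.zeros(labels.shape), role="concentration"
        )
        series = synthesize_multiecho(
            zero, me_params, noise_sd=config.multiecho.noise_sd,
            seed=substream_seed(seed, "noise-baseline"),
        )
        return fit_r2star(
            series,
            noise_floor=config.dosimetry.noise_floor,
            r2star_max_s=config.dosimetry.r2star_max_s,
        )

    baseline_map = fit_baseline()

    @_stage("dose")
    def measure_doses():
        dose_maps, qcs = [], []
        for k, conc_truth in enumerate(truth.true_concentration):
            series = synthesize_multiecho(
                conc_truth, me_params, noise_sd=config.multiecho.noise_sd,
                seed=substream_seed(seed, f"noise-post-{k}"),
            )
            post = fit_r2star(
                series,
                noise_floor=config.dosimetry.noise_floor,
                r2star_max_s=config.dosimetry.r2star_max_s,
            )
            conc, qc = concentration_map(post, baseline_map, constants)
            dose_maps.append(dose_map(conc, constants, cumulative_fraction_index=k + 1))
            qcs.append(qc)
        return dose_maps, qcs

    dose_maps, qcs = measure_doses()
    final_dose = dose_maps[-1]
    final_conc = final_dose.dose.with_values(
        final_dose.dose.values / constants.gy_per_mg_ml, role="concentration"
    )

    # --- dce --------------------------------------------------------------
    @_stage("dce")
    def run_dce():
        params = DceParams(
            n_frames=config.dce.n_frames,
            frame_interval_s=config.dce.frame_interval_s,
            s0=config.dce.s0,
            pe_max_percent=config.dce.pe_max_percent,
            t0_s=config.dce.t0_s,
            rise_s=config.dce.rise_s,
            noise_sd=config.dce.noise_sd,
            reduced_perfusion_lobes=config.dce.reduced_perfusion_lobes,
        )
        series = synthesize_dce(
            labels, truth.lobe_perfusion_fraction, params,
            seed=substream_seed(seed, "dce"),
        )
        result = analyze_dce(
            series,
            labels,
            baseline_frames=config.analysis.baseline_frames,
            window_frames=config.analysis.window_frames,
            noise_threshold=config.analysis.noise_threshold_pe,
            conventional_pe=config.analysis.conventional_pe,
        )
        return series, result

    dce_series, perfusion_result = run_dce()

    # --- metrics ----------------------------------------------------------
    @_stage("metrics")
    def compute_metrics():
        liver_mask = labels.liver_mask
        his = [homogeneity_index(dm.dose, mask=liver_mask) for dm in dose_maps]
        schedule = truth.schedule
        traj = hi_trajectory(
            dose_maps,
            schedule.cumulative_delivered_mg,
            labels.liver_volume_ml(),
            mask=liver_mask,
        ) if len(dose_maps) >= 2 else None
        return his, traj

    his, trajectory = compute_metrics()

    # --- associate --------------------------------------------------------
    @_stage("associate")
    def associate():
        counts = microsphere_counts(final_conc, labels, truth.spheres)
        summary_tbl = lobe_dose_summary(final_dose, labels)
        return correlate_perfusion_deposition(
            perfusion_result, counts,
            mean_dose_gy=summary_tbl["mean_dose_gy"].to_numpy(),
        ), counts, summary_tbl

    lobe_table, counts, dose_table = associate()

    # --- report -----------------------------------------------------------
    import holoperf

    summary = {
        "config": json.loads(config.model_dump_json()),
        "seed": seed,
        "condition": {
            "name": condition.name,
            "ha_flow_per_gram_ml_min_g": condition.ha_flow_per_gram,
            "pv_flow_per_gram_ml_min_g": condition.pv_flow_per_gram,
            "mixing": condition.mixing,
        },
        "liver_volume_ml": labels.liver_volume_ml(),
        "lobe_volumes_ml": labels.lobe_volumes_ml().tolist(),
        "total_delivered_mg": truth.schedule.total_delivered_mg,
        "HI_per_fraction": [s.hi for s in his],
        "dose_stats_final": {
            "d2_gy": his[-1].d2,
            "d98_gy": his[-1].d98,
            "dmean_gy": his[-1].dmean,
            "hi": his[-1].hi,
        },
        "lobe_table": json.loads(lobe_table.table.to_json(orient="records")),
        "lobe_dose_table": json.loads(dose_table.to_json(orient="records")),
        "pearson_r": lobe_table.r,
        "pearson_p": lobe_table.p_value,
        "correlation_category": lobe_table.category,
        "qc": qcs,
        "versions": {
            "python": platform.python_version(),
            "holoperf": holoperf.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if trajectory is not None:
        summary["hi_trajectory"] = json.loads(trajectory.to_json(orient="records"))
    summary = _round_floats(summary)

    if outdir is not None:
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True)
        )
        lobe_table.table.to_csv(outdir / "lobe_table.csv", index=False)
        dose_table.to_csv(outdir / "lobe_dose_table.csv", index=False)
        if trajectory is not None:
            trajectory.to_csv(outdir / "hi_trajectory.csv", index=False)
        if write_volumes:
            io.write_label_map(labels, outdir / "labels.nii.gz")
            for k, conc in enumerate(truth.true_concentration, start=1):
                io.write_volume(conc, outdir / f"truth_concentration_f{k:02d}.nii.gz")
            io.write_volume(final_dose.dose, outdir / "dose_final.nii.gz")
            io.write_dynamic(dce_series, outdir / "dce.nii.gz")
    return summary
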