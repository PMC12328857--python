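"""Run configuration.

A pipeline run is a pure function of (config, seed): the config captures
every tunable of the phantom, the acquisition simulation, and the analysis.
Validation is handled by pydantic; ``PipelineConfig.model_json_schema()``
publishes the schema.
"""

from __future__ import annotations

from typing import Optional, Sequence

from pydantic import BaseModel, Field, field_validator, model_validator

from .phantom.deposition import HA_FLOW_BY_CONDITION, MIXING_BY_CONDITION

__all__ = ["PipelineConfig"]


class GridConfig(BaseModel):
    shape: tuple[int, int, int] = (96, 96, 64)
    spacing_mm: float = Field(2.0, gt=0)


class PhantomConfig(BaseModel):
    volume_fractions: tuple[float, float, float, float, float] = (
        0.30, 0.20, 0.20, 0.22, 0.08,
    )
    target_volume_ml: Optional[float] = Field(None, gt=0)
    tree_generations: int = Field(7, ge=2)
    root_radius_mm: float = Field(1.5, gt=0)
    perfusion_jitter: float = Field(0.2, ge=0, lt=1)
    perfusion_override: Optional[Sequence[float]] = None

    @field_validator("volume_fractions")
    @classmethod
    def _positive(cls, v):
        if any(x <= 0 for x in v):
            raise ValueError("volume fractions must be positive")
        return v


class ConditionConfig(BaseModel):
    name: str = "medium"
    mixing: Optional[float] = Field(None, ge=0, le=1)

    @field_validator("name")
    @classmethod
    def _known(cls, v):
        if v not in HA_FLOW_BY_CONDITION:
            raise ValueError(f"condition must be one of {sorted(HA_FLOW_BY_CONDITION)}")
        return v

    @property
    def ha_flow_per_gram(self) -> float:
        return HA_FLOW_BY_CONDITION[self.name]

    @property
    def effective_mixing(self) -> float:
        return MIXING_BY_CONDITION[self.name] if self.mixing is None else self.mixing


class ScheduleConfig(BaseModel):
    masses_mg: tuple[float, ...] = (250.0,) * 5
    residual_fraction: float = Field(0.0, ge=0, lt=1)

    @field_validator("masses_mg")
    @classmethod
    def _positive(cls, v):
        if not v or any(m <= 0 for m in v):
            raise ValueError("fraction masses must be positive")
        return v


class DepositionConfig(BaseModel):
    n_packets_per_fraction: int = Field(10_000, ge=100)
    gamma: float = Field(3.0, gt=0)
    lam: float = Field(0.25, ge=0)
    tau_g: float = Field(2.0, gt=0)
    blur_sigma_vox: float = Field(1.0, ge=0)


class SpheresConfig(BaseModel):
    diameter_um: float = Field(30.0, gt=0)
    density_g_ml: float = Field(1.4, gt=0)


class MultiEchoConfig(BaseModel):
    n_echoes: int = Field(10, ge=3)
    te1_ms: float = Field(1.7, gt=0)
    delta_te_ms: float = Field(1.35, gt=0)
    s0: float = Field(1000.0, gt=0)
    r2star_baseline_s: float = Field(35.0, ge=0)
    noise_sd: float = Field(0.0, ge=0)


class DceConfig(BaseModel):
    n_frames: int = Field(200, ge=20)
    frame_interval_s: float = Field(0.86, gt=0)
    s0: float = Field(500.0, gt=0)
    pe_max_percent: float = Field(60.0, gt=0, lt=100)
    t0_s: float = Field(30.0, ge=0)
    rise_s: float = Field(45.0, gt=0)
    noise_sd: float = Field(0.0, ge=0)
    reduced_perfusion_lobes: tuple[int, ...] = ()


class DosimetryConfig(BaseModel):
    specific_activity_mbq_mg: float = Field(12.0, gt=0)
    relaxivity_s_per_mg_ml: float = Field(90.0, gt=0)
    dose_factor_gy_kg_gbq: float = Field(15.87, gt=0)
    tissue_density_g_ml: float = Field(1.04, gt=0)
    noise_floor: float = Field(0.0, ge=0)
    r2star_max_s: float = Field(2000.0, gt=0)


class AnalysisConfig(BaseModel):
    baseline_frames: int = Field(10, ge=1)
    window_frames: int = Field(5, ge=3)
    noise_threshold_pe: float = Field(1.0, ge=0)
    conventional_pe: bool = False


class MicroCTConfig(BaseModel):
    enabled: bool = False
    spacing_mm: float = Field(0.03, gt=0)
    block_mm: float = Field(6.0, gt=0, le=20.0)
    threshold_hu: float = 350.0


class PipelineConfig(BaseModel):
    """Complete, validated configuration of one phantom-to-report run."""

    seed: int = 0
    grid: GridConfig = GridConfig()
    phantom: PhantomConfig = PhantomConfig()
    condition: ConditionConfig = ConditionConfig()
    schedule: ScheduleConfig = ScheduleConfig()
    deposition: DepositionConfig = DepositionConfig()
    spheres: SpheresConfig = SpheresConfig()
    multiecho: MultiEchoConfig = MultiEchoConfig()
    dce: DceConfig = DceConfig()
    dosimetry: DosimetryConfig = DosimetryConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    microct: MicroCTConfig = MicroCTConfig()

    @model_validator(mode="after")
    def _baseline_fits(self):
        if self.analysis.baseline_frames >= self.dce.n_frames:
            raise ValueError("baseline_frames must be < dce.n_frames")
        return self

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import json
        from pathlib import Path

        return cls.model_validate(json.loads(Path(path).read_text()))
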