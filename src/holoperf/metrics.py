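"""Dose-distribution statistics and micro-CT segmentation.

Dose-volume metrics follow the radiotherapy DVH convention: ``Dp%`` is the
dose exceeded by exactly p% of the masked volume, i.e. the (100 - p)-th
percentile of the voxel doses with linear interpolation between order
statistics.  The homogeneity index is

    HI = (D2% - D98%) / Dmean,

lower meaning more homogeneous; it is invariant under dose scaling.  All
in-mask voxels — including zero-dose ones — enter the percentiles and the
mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import DomainError, VolumeGrid
from .dosimetry import DoseMap

__all__ = [
    "DoseStats",
    "MicroCTParams",
    "dose_percentile",
    "homogeneity_index",
    "hi_trajectory",
    "dvh",
    "segment_microct",
]


@dataclass(frozen=True)
class DoseStats:
    """Near-maximum D2%, near-minimum D98%, mean dose, and HI."""

    d2: float
    d98: float
    dmean: float
    hi: float

    def __post_init__(self):
        if np.isfinite(self.d2) and np.isfinite(self.d98) and self.d2 < self.d98:
            raise ValueError("D2% must be >= D98%")


def _masked_doses(dose, mask=None) -> np.ndarray:
    """Finite voxel doses of a DoseMap / VolumeGrid / array, optionally masked."""
    if isinstance(dose, DoseMap):
        dose = dose.dose
    if isinstance(dose, VolumeGrid):
        values = dose.values
        if mask is None:
            mask = dose.mask
    else:
        values = np.asarray(dose)
    vals = values[mask] if mask is not None else values.ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise DomainError("empty mask: no finite voxel doses")
    return np.asarray(vals, dtype=float)


def dose_percentile(dose, p: float, mask=None) -> float:
    """Dp% — the dose exceeded by exactly p% of the masked volume.

    Computed as the (100 - p)-th percentile of the voxel doses with linear
    interpolation between order statistics.  Zero-dose voxels are included.
    """
    if not (0.0 < p < 100.0):
        raise DomainError("p must be in (0, 100)")
    vals = _masked_doses(dose, mask)
    return float(np.percentile(vals, 100.0 - p, method="linear"))


def homogeneity_index(dose, mask=None) -> DoseStats:
    """Full dose statistics including HI = (D2% - D98%) / Dmean.

    A zero (or undefined) mean dose yields NaN statistics with ``hi`` NaN
    — flagged, not silently zeroed.
    """
    vals = _masked_doses(dose, mask)
    d2 = float(np.percentile(vals, 98.0, method="linear"))
    d98 = float(np.percentile(vals, 2.0, method="linear"))
    dmean = float(vals.mean())
    if dmean <= 0:
        return DoseStats(d2=d2, d98=d98, dmean=dmean, hi=float("nan"))
    return DoseStats(d2=d2, d98=d98, dmean=dmean, hi=(d2 - d98) / dmean)


def hi_trajectory(
    dose_maps: list, cumulative_mass_mg, liver_volume_ml: float, mask=None
) -> pd.DataFrame:
    """HI against administered microsphere loading (mg/mL of liver).

    Parameters
    ----------
    dose_maps : list of DoseMap / VolumeGrid
        One map per cumulative fraction, co-registered.
    cumulative_mass_mg : sequence
        Cumulative delivered mass after each fraction (mg), same length.
    liver_volume_ml : float
        Liver volume for the loading axis.

    Returns a DataFrame with ``mg_per_ml`` and ``hi`` (plus the full dose
    statistics) per cumulative fraction.
    """
    cumulative_mass_mg = np.asarray(cumulative_mass_mg, dtype=float)
    if len(dose_maps) < 2:
        raise DomainError("trajectory needs >= 2 points")
    if len(dose_maps) != cumulative_mass_mg.size:
        raise DomainError("one cumulative mass per dose map required")
    if liver_volume_ml <= 0:
        raise DomainError("liver volume must be > 0")
    shapes = set()
    for dm in dose_maps:
        grid = dm.dose if isinstance(dm, DoseMap) else dm
        shapes.add(np.asarray(grid.values if isinstance(grid, VolumeGrid) else grid).shape)
    if len(shapes) > 1:
        raise DomainError(f"inconsistent geometry across maps: {sorted(shapes)}")
    rows = []
    for dm, mass in zip(dose_maps, cumulative_mass_mg):
        stats = homogeneity_index(dm, mask=mask)
        rows.append(
            dict(mg_per_ml=mass / liver_volume_ml, hi=stats.hi, d2=stats.d2,
                 d98=stats.d98, dmean=stats.dmean)
        )
    return pd.DataFrame(rows)


def dvh(dose, mask=None, n_bins: int = 256) -> pd.DataFrame:
    """Cumulative dose-volume histogram: volume fraction receiving >= dose."""
    vals = _masked_doses(dose, mask)
    edges = np.linspace(0.0, float(vals.max()) if vals.max() > 0 else 1.0, n_bins)
    frac = [(vals >= e).mean() for e in edges]
    return pd.DataFrame({"dose_gy": edges, "volume_fraction": frac})


# ---------------------------------------------------------------------------
# micro-CT segmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MicroCTParams:
    """Micro-CT segmentation: threshold 350 HU, 26-connectivity."""

    threshold_hu: float = 350.0
    connectivity: int = 26

    def __post_init__(self):
        if not np.isfinite(self.threshold_hu):
            raise ValueError("threshold must be finite")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def segment_microct(
    volume: VolumeGrid, params: MicroCTParams = MicroCTParams()
) -> tuple[np.ndarray, pd.DataFrame]:
    """Threshold segmentation of microsphere-filled vessels.

    Returns the binary mask (``volume >= threshold``) and a per-component
    table with component volume (mm^3) and a radius estimate (mm): the
    maximum of the Euclidean distance transform inside the component, i.e.
    the radius of the largest inscribed sphere.  An empty mask yields an
    empty table, not an error.
    """
    mask = volume.values >= params.threshold_hu
    if not mask.any():
        return mask, pd.DataFrame(
            columns=["component", "n_voxels", "volume_mm3", "radius_mm"]
        ).astype({"component": int, "n_voxels": int})
    labels, n_comp = ndimage.label(mask, structure=_STRUCTURES[params.connectivity])
    voxel_mm3 = float(np.prod(volume.spacing))
    edt = ndimage.distance_transform_edt(mask, sampling=volume.spacing)
    idx = np.arange(1, n_comp + 1)
    counts = ndimage.sum_labels(np.ones_like(labels), labels, index=idx)
    max_edt = ndimage.labeled_comprehension(edt, labels, idx, np.max, float, 0.0)
    table = pd.DataFrame(
        {
            "component": idx,
            "n_voxels": counts.astype(int),
            "volume_mm3": counts * voxel_mm3,
            "radius_mm": max_edt,
        }
    )
    return mask, table
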