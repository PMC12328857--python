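"""DCE-MRI perfusion analysis.

Per-lobe time-intensity curves are converted to percent enhancement with
the denominator convention used throughout this pipeline,

    PE(t) = 100 * (S1 - S0) / S1,

where S0 is the mean pre-contrast lobe signal and S1 the post-injection
lobe signal (note the *post-injection* denominator; the conventional
(S1 - S0) / S0 form is available behind a flag for sensitivity analysis).
The maximum slope of the wash-in period of the PE curve is the lobe's
relative perfusion-rate measure; relative perfusion shares are the slopes
normalised to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import DomainError, DynamicSeries, LobeLabelMap

__all__ = [
    "TimeIntensityCurve",
    "PerfusionResult",
    "extract_tic",
    "percent_enhancement",
    "max_washin_slope",
    "relative_perfusion",
    "analyze_dce",
]


@dataclass
class TimeIntensityCurve:
    """Lobe-mean signal over time.

    ``s0_lobe`` is the mean signal over the lobe and the baseline frames;
    ``s_t`` the lobe-mean signal per frame; ``times_s`` the frame times.
    """

    lobe: int
    s0_lobe: float
    s_t: np.ndarray
    times_s: np.ndarray

    @property
    def frame_interval_s(self) -> float:
        return float(self.times_s[1] - self.times_s[0])


@dataclass
class PerfusionResult:
    """Per-lobe maximum wash-in PE slopes and relative perfusion shares."""

    max_slope: np.ndarray  # %/s, lobes 1..5
    relative_perfusion: np.ndarray  # sums to 1
    washin_window: list  # (start, stop) frame indices per lobe
    non_enhancing: np.ndarray = field(
        default_factory=lambda: np.zeros(5, dtype=bool)
    )


def extract_tic(
    series: DynamicSeries, labels: LobeLabelMap, baseline_frames: int = 10
) -> list[TimeIntensityCurve]:
    """Per-lobe time-intensity curves.

    ``baseline_frames`` frames (default 10) are assumed to precede contrast
    arrival; their lobe-mean defines S0.
    """
    if baseline_frames < 1:
        raise DomainError("baseline_frames must be >= 1")
    if baseline_frames >= series.n_frames:
        raise DomainError(
            f"baseline_frames ({baseline_frames}) must be < n_frames "
            f"({series.n_frames})"
        )
    if series.shape != labels.shape:
        raise DomainError("series and label map do not share geometry")
    data = series.data()
    times = series.times_s
    curves = []
    for lobe in range(1, 6):
        mask = labels.labels == lobe
        if not mask.any():
            raise DomainError(f"empty lobe {lobe} ({labels.names[lobe]})")
        s_t = data[mask, :].mean(axis=0)
        s0 = float(s_t[:baseline_frames].mean())
        curves.append(TimeIntensityCurve(lobe=lobe, s0_lobe=s0, s_t=s_t, times_s=times))
    return curves


def percent_enhancement(
    tic: TimeIntensityCurve, conventional: bool = False
) -> np.ndarray:
    """Percent-enhancement curve of a TIC.

    Default: ``PE = 100 * (S1 - S0) / S1`` (post-injection denominator).
    With ``conventional=True``: ``PE = 100 * (S1 - S0) / S0``.  Frames with
    non-positive signal are NaN (undefined), never silently clipped.
    """
    s = np.asarray(tic.s_t, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if conventional:
            pe = 100.0 * (s - tic.s0_lobe) / tic.s0_lobe
        else:
            pe = 100.0 * (s - tic.s0_lobe) / s
    pe = np.where(s > 0, pe, np.nan)
    return pe


def max_washin_slope(
    pe: np.ndarray,
    frame_interval_s: float,
    window_frames: int = 5,
    noise_threshold: float = 1.0,
    washin_lo: float = 0.05,
    washin_hi: float = 0.95,
) -> tuple[float, tuple[int, int], bool]:
    """Maximum wash-in slope of a PE curve (%/s).

    The wash-in window runs from the last frame with PE below
    ``washin_lo`` x max(PE) to the first frame reaching ``washin_hi`` x
    max(PE); the slope is the maximum over sliding ``window_frames``-frame
    linear regressions inside the window.  A flat curve (max PE at or below
    ``noise_threshold`` percent) is flagged non-enhancing and returns slope
    0 — the study saw no flat curves, which would indicate non-perfused
    tissue.

    Returns (max_slope, (start, stop), non_enhancing_flag).
    """
    pe = np.asarray(pe, dtype=float)
    finite = np.isfinite(pe)
    if frame_interval_s <= 0:
        raise DomainError("frame_interval_s must be > 0")
    if finite.sum() < window_frames:
        raise DomainError("too few defined PE frames for slope estimation")
    peak = np.nanmax(pe)
    if not np.isfinite(peak) or peak <= noise_threshold:
        return 0.0, (0, pe.size), True

    below = np.nonzero(pe < washin_lo * peak)[0]
    start = int(below[-1]) if below.size else 0
    above = np.nonzero(pe >= washin_hi * peak)[0]
    stop = int(above[0]) + 1 if above.size else pe.size
    if stop - start < window_frames:
        start = max(0, stop - window_frames)
        if stop - start < window_frames:
            stop = min(pe.size, start + window_frames)

    t = frame_interval_s * np.arange(pe.size)
    best = -np.inf
    for i in range(start, stop - window_frames + 1):
        seg = pe[i : i + window_frames]
        if not np.all(np.isfinite(seg)):
            continue
        slope = np.polyfit(t[i : i + window_frames], seg, 1)[0]
        best = max(best, slope)
    if not np.isfinite(best):
        raise DomainError("no fully defined window inside the wash-in period")
    return float(best), (start, stop), False


def relative_perfusion(slopes: np.ndarray) -> np.ndarray:
    """Relative perfusion shares: slope_l / sum(slopes).

    Raises if no lobe has a positive slope.
    """
    slopes = np.asarray(slopes, dtype=float)
    if np.any(slopes < 0):
        raise DomainError("slopes must be >= 0")
    total = slopes.sum()
    if total <= 0:
        raise DomainError("all slopes zero: no perfused lobe")
    return slopes / total


def analyze_dce(
    series: DynamicSeries,
    labels: LobeLabelMap,
    baseline_frames: int = 10,
    window_frames: int = 5,
    noise_threshold: float = 1.0,
    conventional_pe: bool = False,
) -> PerfusionResult:
    """Full DCE chain: TICs -> PE -> max wash-in slopes -> relative perfusion."""
    curves = extract_tic(series, labels, baseline_frames=baseline_frames)
    slopes = np.zeros(5)
    windows = []
    flags = np.zeros(5, dtype=bool)
    for i, tic in enumerate(curves):
        pe = percent_enhancement(tic, conventional=conventional_pe)
        slope, window, flag = max_washin_slope(
            pe,
            tic.frame_interval_s,
            window_frames=window_frames,
            noise_threshold=noise_threshold,
        )
        slopes[i] = max(slope, 0.0)
        windows.append(window)
        flags[i] = flag
    return PerfusionResult(
        max_slope=slopes,
        relative_perfusion=relative_perfusion(slopes),
        washin_window=windows,
        non_enhancing=flags,
    )
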