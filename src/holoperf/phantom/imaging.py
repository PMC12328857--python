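"""Synthetic MR and micro-CT signal generation.

Multi-echo magnitude images follow a mono-exponential decay
``S(TE) = S0 * exp(-(R2*_0 + r2* . C) * TE)`` with Rician noise, the
standard model for magnitude MR.  Dynamic contrast series are built
per-lobe so that the analytic maximum slope of the *percent-enhancement*
curve (the quantity the analysis estimates) is exactly proportional to the
lobe's ground-truth perfusion share.  Micro-CT blocks render the deposition
truth of a sampled subtree as attenuating cylinders on a soft-tissue
background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..grids import (
    DomainError,
    DynamicSeries,
    LobeLabelMap,
    MultiEchoSeries,
    VolumeGrid,
    default_echo_times,
)
from ..seeding import substream
from .deposition import PhantomTruth
from .tree import ArterialTree

__all__ = [
    "MultiEchoParams",
    "DceParams",
    "MicroCTParamsSynth",
    "synthesize_multiecho",
    "synthesize_dce",
    "synthesize_microct",
    "washin_shape",
    "analytic_max_pe_slope",
]


# ---------------------------------------------------------------------------
# multi-echo gradient echo
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MultiEchoParams:
    """Acquisition and tissue parameters for the T2*-weighted sequence.

    Defaults: 10 echoes, TE1 = 1.7 ms, deltaTE = 1.35 ms; proton-density
    signal 1000 a.u.; tissue baseline R2*_0 = 35 s^-1; holmium relaxivity
    r2* = 90 s^-1 per mg/mL at 1.5 T.
    """

    echo_times_ms: tuple[float, ...] = tuple(default_echo_times())
    s0: float = 1000.0
    r2star_baseline_s: float = 35.0
    relaxivity_s_per_mg_ml: float = 90.0


def synthesize_multiecho(
    concentration: VolumeGrid,
    params: MultiEchoParams = MultiEchoParams(),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MultiEchoSeries:
    """Simulate the holmium-sensitive multi-echo series for a concentration map.

    Signal outside the concentration mask (non-tissue) is zero plus noise.
    Rician noise of parameter ``noise_sd`` is applied per echo:
    ``|S + n1 + i n2|`` with n1, n2 ~ N(0, noise_sd).
    """
    conc = np.asarray(concentration.values, dtype=float)
    if np.any(conc < 0):
        raise DomainError("concentration must be >= 0 everywhere")
    tes_s = np.asarray(params.echo_times_ms, dtype=float) / 1000.0
    r2star = params.r2star_baseline_s + params.relaxivity_s_per_mg_ml * conc
    signal = params.s0 * np.exp(-r2star[..., None] * tes_s)
    if concentration.mask is not None:
        signal = signal * concentration.mask[..., None]
    if noise_sd > 0:
        rng = substream(seed, "noise-multiecho")
        n1 = rng.normal(0.0, noise_sd, size=signal.shape)
        n2 = rng.normal(0.0, noise_sd, size=signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)
    return MultiEchoSeries.from_array(
        signal,
        params.echo_times_ms,
        spacing=concentration.spacing,
        origin=concentration.origin,
        mask=None if concentration.mask is None else concentration.mask.copy(),
    )


# ---------------------------------------------------------------------------
# dynamic contrast-enhanced series
# ---------------------------------------------------------------------------

def washin_shape(x: np.ndarray) -> np.ndarray:
    """Quintic smoothstep wash-in: 0 for x <= 0, 1 for x >= 1, C^2 in between.

    Its maximum derivative is 15/8 at x = 1/2.  Compact support keeps the
    pre-contrast baseline exactly flat within a finite acquisition, which a
    logistic's infinite tails cannot.
    """
    x = np.clip(x, 0.0, 1.0)
    return x**3 * (10.0 - 15.0 * x + 6.0 * x**2)


#: Maximum derivative of :func:`washin_shape`.
_SMOOTHSTEP_MAX_SLOPE = 15.0 / 8.0


@dataclass(frozen=True)
class DceParams:
    """Dynamic contrast acquisition and enhancement parameters.

    ``pe_max_percent`` is the percent-enhancement amplitude of the
    best-perfused lobe; lobe ``l`` gets amplitude
    ``pe_max_percent * p_l / max(p)`` so the analytic maximum PE slope is
    exactly proportional to the perfusion share ``p_l``.  ``t0_s`` and
    ``rise_s`` position the wash-in inside the 200-frame acquisition.
    """

    n_frames: int = 200
    frame_interval_s: float = 0.86
    s0: float = 500.0
    pe_max_percent: float = 60.0
    t0_s: float = 30.0
    rise_s: float = 45.0
    noise_sd: float = 0.0
    #: lobes (1-based labels) with delayed, damped wash-in
    reduced_perfusion_lobes: tuple[int, ...] = ()
    reduced_delay_s: float = 25.0
    reduced_damping: float = 0.5


def analytic_max_pe_slope(params: DceParams, perfusion_fraction: np.ndarray) -> np.ndarray:
    """Closed-form maximum PE slope (%/s) per lobe under ``params``."""
    p = np.asarray(perfusion_fraction, dtype=float)
    amp = params.pe_max_percent * p / p.max()
    slopes = amp * _SMOOTHSTEP_MAX_SLOPE / params.rise_s
    for lobe in params.reduced_perfusion_lobes:
        slopes[lobe - 1] *= params.reduced_damping
    return slopes


def synthesize_dce(
    label_map: LobeLabelMap,
    perfusion_fraction: np.ndarray,
    params: DceParams = DceParams(),
    seed: int = 0,
) -> DynamicSeries:
    """Simulate the dynamic contrast series for known lobe perfusion shares.

    Per-lobe percent enhancement follows
    ``PE_l(t) = A_l * washin((t - t0) / rise)`` with ``A_l`` proportional
    to the lobe's perfusion share; the voxel signal is recovered by
    inverting the percent-enhancement transform,
    ``S = S0 / (1 - PE/100)``, so that analysing the noiseless series
    returns the ground-truth relative perfusion exactly.  Gaussian temporal
    noise of SD ``noise_sd`` is added per voxel and frame.
    """
    p = np.asarray(perfusion_fraction, dtype=float)
    if p.size != 5 or np.any(p <= 0):
        raise ValueError("perfusion_fraction must be 5 positive shares")
    if params.pe_max_percent <= 0:
        raise DomainError("enhancement amplitude must be > 0")
    if params.pe_max_percent >= 100:
        raise DomainError("percent-enhancement amplitude must be < 100")
    times = params.frame_interval_s * np.arange(params.n_frames)

    amp = params.pe_max_percent * p / p.max()
    t0 = np.full(5, params.t0_s)
    damp = np.ones(5)
    for lobe in params.reduced_perfusion_lobes:
        t0[lobe - 1] += params.reduced_delay_s
        damp[lobe - 1] = params.reduced_damping

    signal = np.zeros(label_map.shape + (params.n_frames,))
    for lobe in range(1, 6):
        pe_t = amp[lobe - 1] * damp[lobe - 1] * washin_shape(
            (times - t0[lobe - 1]) / params.rise_s
        )
        s_t = params.s0 / (1.0 - pe_t / 100.0)
        signal[label_map.labels == lobe, :] = s_t
    if params.noise_sd > 0:
        rng = substream(seed, "noise-dce")
        signal = signal + rng.normal(0.0, params.noise_sd, size=signal.shape)
    return DynamicSeries.from_array(
        signal,
        params.frame_interval_s,
        spacing=label_map.spacing,
        origin=label_map.origin,
    )


# ---------------------------------------------------------------------------
# micro-CT
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MicroCTParamsSynth:
    """Synthesis parameters for a micro-CT tissue block.

    Lodged microspheres are rendered as a packed plug at the distal end of
    their segment: plug volume = mass / (sphere density x packing
    fraction), at ``vessel_hu`` (well above the 350 HU segmentation
    threshold).  A plug thinner than one voxel is painted with
    partial-volume attenuation and fades below the threshold — sparse
    deposits in large vessels are invisible, exactly as on real
    reconstructions.  Parenchyma background is N(40, 15) HU.
    """

    spacing_mm: float = 0.03
    block_mm: float = 20.0
    background_hu: float = 40.0
    background_sd_hu: float = 15.0
    vessel_hu: float = 1200.0
    sphere_density_mg_mm3: float = 1.4
    packing_fraction: float = 0.6


def synthesize_microct(
    tree: ArterialTree,
    segment_mass_mg: np.ndarray,
    params: MicroCTParamsSynth = MicroCTParamsSynth(),
    center_node: int | None = None,
    seed: int = 0,
) -> VolumeGrid:
    """Render a micro-CT tissue block around a subtree of one lobe's tree.

    Parameters
    ----------
    tree : ArterialTree
        The lobe tree sampled.
    segment_mass_mg : (n_nodes,) float
        Cumulative deposited mass per segment of that tree.
    center_node : int, optional
        The block is centred on this node's position — like cutting a
        tissue sample around a vascular branch point.  Defaults to a
        seeded choice among generation-4 nodes (or the deepest internal
        level available).  Every tree segment passing through the block is
        rendered, whatever its generation.

    Raises
    ------
    ValueError
        For an empty tree or a block larger than the 20 mm sample size.
    """
    if params.block_mm > 20.0 + 1e-9:
        raise ValueError("sample blocks are at most 20 mm on a side")
    segment_mass_mg = np.asarray(segment_mass_mg, dtype=float)
    if segment_mass_mg.shape != (tree.n_nodes,):
        raise ValueError("segment_mass_mg must have one entry per tree node")
    if tree.n_nodes < 2:
        raise ValueError("empty tree")
    rng = substream(seed, "microct")
    if center_node is None:
        level = min(2, tree.generations - 2)
        lo, hi = 2**level - 1, 2 ** (level + 1) - 1
        center_node = int(rng.integers(lo, hi))

    n_side = int(round(params.block_mm / params.spacing_mm))
    shape = (n_side, n_side, n_side)
    hu = rng.normal(params.background_hu, params.background_sd_hu, size=shape)

    block_center = np.full(3, params.block_mm / 2.0)
    shift = block_center - tree.node_pos[center_node]

    axes = [np.arange(n) * params.spacing_mm for n in shape]
    for node in range(1, tree.n_nodes):
        mass = segment_mass_mg[node]
        if mass <= 0:
            continue
        r = tree.radius[node]
        p0 = tree.node_pos[tree.parent(node)] + shift
        p1 = tree.node_pos[node] + shift
        length = float(np.linalg.norm(p1 - p0))
        if length == 0:
            continue
        # packed plug at the distal end of the segment
        plug_mm3 = mass / (params.sphere_density_mg_mm3 * params.packing_fraction)
        plug_len = min(length, plug_mm3 / (np.pi * r**2))
        frac = min(1.0, plug_len / params.spacing_mm)  # partial volume
        hu_vessel = params.background_hu + frac * (
            params.vessel_hu - params.background_hu
        )
        draw_len = max(plug_len, params.spacing_mm)
        p_start = p1 + (p0 - p1) * min(1.0, draw_len / length)
        _paint_cylinder(hu, axes, p_start, p1, r, hu_vessel)
    return VolumeGrid(
        values=hu,
        spacing=(params.spacing_mm,) * 3,
        role="hu",
    )


def _paint_cylinder(hu, axes, p0, p1, radius, value) -> None:
    """Set voxels within ``radius`` of the segment p0-p1 to ``value``
    (maximum with the existing content), working in the cylinder's bbox."""
    lo = np.minimum(p0, p1) - radius
    hi = np.maximum(p0, p1) + radius
    sl = []
    for a in range(3):
        i0 = int(np.searchsorted(axes[a], lo[a]))
        i1 = int(np.searchsorted(axes[a], hi[a], side="right"))
        if i0 >= i1 or i1 <= 0 or i0 >= axes[a].size:
            return
        sl.append(slice(max(i0, 0), min(i1, axes[a].size)))
    xx, yy, zz = np.meshgrid(
        axes[0][sl[0]], axes[1][sl[1]], axes[2][sl[2]], indexing="ij"
    )
    pts = np.stack([xx, yy, zz], axis=-1)
    d = pts - p0
    axis = p1 - p0
    seg_len2 = float(axis @ axis)
    if seg_len2 == 0:
        inside = np.linalg.norm(d, axis=-1) <= radius
    else:
        t = (d @ axis) / seg_len2
        radial = np.linalg.norm(d - t[..., None] * axis, axis=-1)
        # flat-ended cylinder: no spherical caps beyond the plug
        inside = (radial <= radius) & (t >= 0.0) & (t <= 1.0)
    region = hu[sl[0], sl[1], sl[2]]
    region[inside] = np.maximum(region[inside], value)
    hu[sl[0], sl[1], sl[2]] = region
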