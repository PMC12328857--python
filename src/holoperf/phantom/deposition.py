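"""Flow-rate-dependent microsphere deposition.

Microspheres are transported as packets through the arterial trees.  How
faithfully a packet follows the blood flow is governed by a *mixing*
parameter in [0, 1], the simulator's abstraction of how completely spheres
homogenise with blood before each bifurcation; mixing increases with
hepatic-artery flow rate.  At every bifurcation a packet takes child ``c``
with probability

    p_c = mixing * f_c + (1 - mixing) * g_c,      g_c = f_c**gamma / sum f**gamma

where ``f_c`` is the flow fraction and ``g_c`` a streamline-biased split
(exponent ``gamma``) that over-concentrates packets into the dominant
branch when mixing is poor.  Before each bifurcation the packet may lodge
in the segment it has just traversed, with probability

    p_lodge(gen) = lam * (1 - mixing) * exp(-gen / tau_g),

so poorly mixed, low-flow administrations deposit preferentially in the
proximal (low-generation, large-radius) vessels.  Packets reaching a
terminal lodge there and their mass is spread over the terminal's tissue
territory.  The lobe-level split at the catheter tip follows the same
biased rule applied to the lobe flow fractions.

Mass is conserved exactly: every packet of every fraction lodges somewhere
(or, with a finite per-segment capacity, is redistributed upstream; a full
root raises :class:`StasisError`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ..grids import LobeLabelMap, VolumeGrid
from ..seeding import substream
from .tree import ArterialTree

__all__ = [
    "FlowCondition",
    "FractionSchedule",
    "MicrosphereSpec",
    "PhantomTruth",
    "StasisError",
    "simulate_deposition",
    "lobe_perfusion_fractions",
]

#: Hepatic-artery flow per gram of liver for the three study conditions
#: (mL/min/g); portal-vein flow is held at three times the HA flow.
HA_FLOW_BY_CONDITION = {"low": 0.02, "medium": 0.15, "high": 0.22}

#: Default mixing assigned to each flow condition.  The mapping is an
#: explicit free parameter of the simulator (no quantitative mixing law is
#: available); the defaults reproduce the qualitative homogeneity ordering
#: across conditions.
MIXING_BY_CONDITION = {"low": 0.25, "medium": 0.65, "high": 0.90}


class StasisError(RuntimeError):
    """Raised when segment capacities fill all the way back to the root."""


@dataclass(frozen=True)
class FlowCondition:
    """A machine-perfusion flow condition.

    ``pv_flow_per_gram`` is exactly three times the HA flow.  ``mixing`` is
    the dimensionless transport parameter in [0, 1]; it must increase with
    HA flow across the named conditions.
    """

    name: str
    ha_flow_per_gram: float
    mixing: float

    def __post_init__(self):
        if not (0.0 <= self.mixing <= 1.0):
            raise ValueError(f"mixing must be in [0, 1], got {self.mixing}")
        if self.ha_flow_per_gram <= 0:
            raise ValueError("ha_flow_per_gram must be > 0")

    @property
    def pv_flow_per_gram(self) -> float:
        return 3.0 * self.ha_flow_per_gram

    @classmethod
    def from_name(cls, name: str, mixing: float | None = None) -> "FlowCondition":
        if name not in HA_FLOW_BY_CONDITION:
            raise ValueError(f"unknown condition {name!r}; expected low/medium/high")
        return cls(
            name=name,
            ha_flow_per_gram=HA_FLOW_BY_CONDITION[name],
            mixing=MIXING_BY_CONDITION[name] if mixing is None else mixing,
        )


@dataclass(frozen=True)
class FractionSchedule:
    """Administered microsphere fractions (mg).

    The study schedule is five fractions of 250 mg; the high-dose arm adds
    four fractions of 1,000 mg.  ``residual_fraction`` is the share of each
    fraction retained in the delivery vial (not delivered).
    """

    masses_mg: tuple[float, ...] = (250.0,) * 5
    residual_fraction: float = 0.0

    def __post_init__(self):
        if len(self.masses_mg) == 0 or any(m <= 0 for m in self.masses_mg):
            raise ValueError("fraction masses must be positive")
        if not (0.0 <= self.residual_fraction < 1.0):
            raise ValueError("residual_fraction must be in [0, 1)")

    @classmethod
    def standard(cls) -> "FractionSchedule":
        return cls(masses_mg=(250.0,) * 5)

    @classmethod
    def extended(cls) -> "FractionSchedule":
        return cls(masses_mg=(250.0,) * 5 + (1000.0,) * 4)

    @property
    def n_fractions(self) -> int:
        return len(self.masses_mg)

    @property
    def delivered_masses_mg(self) -> np.ndarray:
        return np.asarray(self.masses_mg) * (1.0 - self.residual_fraction)

    @property
    def total_delivered_mg(self) -> float:
        return float(self.delivered_masses_mg.sum())

    @property
    def cumulative_delivered_mg(self) -> np.ndarray:
        return np.cumsum(self.delivered_masses_mg)


@dataclass(frozen=True)
class MicrosphereSpec:
    """Microsphere geometry and density (default 30.0 um, 1.4 g/mL)."""

    diameter_um: float = 30.0
    density_g_ml: float = 1.4

    def __post_init__(self):
        if self.diameter_um <= 0 or self.density_g_ml <= 0:
            raise ValueError("diameter and density must be > 0")

    @property
    def mass_per_sphere_mg(self) -> float:
        d_cm = self.diameter_um * 1e-4
        volume_ml = np.pi / 6.0 * d_cm**3
        return self.density_g_ml * volume_ml * 1e3  # g -> mg

    @property
    def spheres_per_mg(self) -> float:
        return 1.0 / self.mass_per_sphere_mg


@dataclass
class PhantomTruth:
    """Ground truth of one simulated administration.

    Attributes
    ----------
    label_map : LobeLabelMap
    trees : dict[int, ArterialTree]
        One tree per lobe label.
    lobe_perfusion_fraction : (5,) float
        Share of HA flow per lobe, summing to 1.
    deposited_mass : (n_fractions, n_segments_total) float
        Delivered mass (mg) lodged in each segment, per fraction.  Segments
        are concatenated lobe-by-lobe; see ``segment_lobe`` /
        ``segment_node`` for the mapping.
    segment_lobe, segment_node, segment_generation : (n_segments_total,) int
        Lobe label, within-tree node index, and generation of each segment.
    true_concentration : list[VolumeGrid]
        Holmium concentration (mg/mL) after each cumulative fraction.
    """

    label_map: LobeLabelMap
    trees: dict[int, ArterialTree]
    lobe_perfusion_fraction: np.ndarray
    schedule: FractionSchedule
    condition: FlowCondition
    spheres: MicrosphereSpec
    deposited_mass: np.ndarray
    segment_lobe: np.ndarray
    segment_node: np.ndarray
    segment_generation: np.ndarray
    true_concentration: list[VolumeGrid] = field(default_factory=list)

    @property
    def n_fractions(self) -> int:
        return self.deposited_mass.shape[0]

    def total_deposited_mg(self) -> float:
        return float(self.deposited_mass.sum())

    def lobe_mass_mg(self, upto_fraction: int | None = None) -> np.ndarray:
        """Deposited mass per lobe (mg) over the first ``upto_fraction``
        fractions (all by default)."""
        dm = self.deposited_mass if upto_fraction is None else self.deposited_mass[:upto_fraction]
        per_segment = dm.sum(axis=0)
        out = np.zeros(5)
        for lobe in range(1, 6):
            out[lobe - 1] = per_segment[self.segment_lobe == lobe].sum()
        return out

    def mass_fraction_in_generations(self, gen_max: int = 3) -> float:
        """Fraction of all deposited mass lodged in segments of generation
        1..gen_max (the proximal, large-calibre vessels)."""
        per_segment = self.deposited_mass.sum(axis=0)
        total = per_segment.sum()
        if total == 0:
            return 0.0
        prox = per_segment[self.segment_generation <= gen_max].sum()
        return float(prox / total)

    def segment_mass_for_lobe(self, lobe: int, upto_fraction: int | None = None) -> np.ndarray:
        """Cumulative deposited mass (mg) per tree node of one lobe."""
        dm = self.deposited_mass if upto_fraction is None else self.deposited_mass[:upto_fraction]
        return dm.sum(axis=0)[self.segment_lobe == lobe]

    def mean_lodged_generation(self) -> float:
        """Mass-weighted mean generation of lodged microspheres."""
        per_segment = self.deposited_mass.sum(axis=0)
        return float(
            (per_segment * self.segment_generation).sum() / per_segment.sum()
        )


def lobe_perfusion_fractions(
    label_map: LobeLabelMap,
    seed: int = 0,
    jitter: float = 0.2,
    override=None,
) -> np.ndarray:
    """Ground-truth lobe perfusion fractions.

    By default proportional to lobe volume with a multiplicative jitter of
    +/- ``jitter`` (uniform, seeded), normalised to sum to 1; pass
    ``override`` to fix them exactly.
    """
    if override is not None:
        p = np.asarray(override, dtype=float)
        if p.size != 5 or np.any(p <= 0):
            raise ValueError("perfusion fractions must be 5 positive numbers")
        return p / p.sum()
    rng = substream(seed, "perfusion")
    vols = label_map.lobe_volumes_ml()
    p = vols * rng.uniform(1.0 - jitter, 1.0 + jitter, size=5)
    return p / p.sum()


def _biased_split(f: np.ndarray, mixing: float, gamma: float) -> np.ndarray:
    g = f**gamma
    g = g / g.sum()
    return mixing * f + (1.0 - mixing) * g


def _route_lobe_packets(
    tree: ArterialTree,
    n_packets: int,
    mixing: float,
    gamma: float,
    lam: float,
    tau_g: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Route packets through one lobe tree; returns lodged packet counts per
    node (index = heap node of the segment's child; index 0 unused)."""
    counts = np.zeros(tree.n_nodes, dtype=np.int64)
    if n_packets == 0:
        return counts
    first_leaf = tree.first_terminal
    n_int = first_leaf
    # biased left-child probability at each internal node
    left = tree.flow_fraction[2 * np.arange(n_int) + 1]
    right = tree.flow_fraction[2 * np.arange(n_int) + 2]
    tot = left + right
    f_left = np.where(tot > 0, left / np.maximum(tot, 1e-300), 0.5)
    gl = f_left**gamma
    gr = (1.0 - f_left) ** gamma
    g_left = gl / (gl + gr)
    p_left = mixing * f_left + (1.0 - mixing) * g_left

    nodes = np.zeros(n_packets, dtype=np.int64)
    for level in range(1, tree.generations):
        u = rng.random(nodes.size)
        nodes = 2 * nodes + 1 + (u >= p_left[nodes]).astype(np.int64)
        if level < tree.generations - 1:
            p_lodge = lam * (1.0 - mixing) * np.exp(-level / tau_g)
            if p_lodge > 0:
                lodged = rng.random(nodes.size) < p_lodge
                if lodged.any():
                    counts += np.bincount(nodes[lodged], minlength=tree.n_nodes)
                    nodes = nodes[~lodged]
            if nodes.size == 0:
                break
    if nodes.size:
        counts += np.bincount(nodes, minlength=tree.n_nodes)
    return counts


def _apply_capacity(
    counts: np.ndarray, cap: np.ndarray, generations: int
) -> np.ndarray:
    """Redistribute packet counts exceeding per-segment capacity to the
    parent segment, deepest generation first."""
    out = counts.copy()
    for node in range(out.size - 1, 0, -1):
        excess = out[node] - cap[node]
        if excess > 0:
            out[node] = cap[node]
            parent = (node - 1) // 2
            if parent == 0:
                raise StasisError(
                    "segment capacity exhausted back to the lobe root (stasis)"
                )
            out[parent] += excess
    return out


def _territory_index(tree: ArterialTree):
    """Per-terminal slices into a terminal-sorted view of the lobe voxels."""
    order = np.argsort(tree.territory_terminal, kind="stable")
    sorted_term = tree.territory_terminal[order]
    starts = np.searchsorted(sorted_term, tree.terminal_nodes)
    counts = np.bincount(tree.territory_terminal, minlength=tree.n_nodes)[
        tree.terminal_nodes
    ]
    return order, starts, counts


def _rasterise_fraction(
    trees: dict[int, ArterialTree],
    counts_by_lobe: dict[int, np.ndarray],
    mass_per_packet: float,
    label_map: LobeLabelMap,
    blur_sigma_vox: float,
    territory_idx: dict,
    rng: np.random.Generator,
) -> np.ndarray:
    """Paint one fraction's lodged mass onto the voxel grid (mg per voxel).

    Each terminal packet deposits at a uniformly random voxel of its
    terminal's territory (discrete cluster formation in the capillary bed;
    the resulting counting noise shrinks as fractions accumulate);
    non-terminal mass is painted along the segment centreline.  Each lobe's
    mass is blurred (sigma in voxels), confined to its own lobe mask —
    microspheres do not cross lobar vascular territories — and renormalised
    so the painted lobe mass equals the lodged lobe mass exactly.
    """
    shape = label_map.shape
    spacing = np.asarray(label_map.spacing)
    out = np.zeros(shape)
    for lobe, tree in trees.items():
        counts = counts_by_lobe[lobe]
        lobe_mass = counts.sum() * mass_per_packet
        if lobe_mass == 0:
            continue
        grid = np.zeros(shape)
        # terminals: each packet lodges at a random territory voxel
        order, starts, terr_counts = territory_idx[lobe]
        term = tree.terminal_nodes
        term_packets = counts[term]
        has_mass = term_packets > 0
        if has_mass.any():
            rows = []
            for ti in np.nonzero(has_mass)[0]:
                n_pack = int(term_packets[ti])
                draw = rng.integers(0, terr_counts[ti], size=n_pack)
                rows.append(order[starts[ti] + draw])
            rows = np.concatenate(rows)
            tv = tree.territory_voxels[rows]
            np.add.at(
                grid, (tv[:, 0], tv[:, 1], tv[:, 2]),
                np.full(rows.size, mass_per_packet),
            )
        # non-terminals: centreline painting
        for node in np.nonzero(counts[: tree.first_terminal])[0]:
            if node == 0:
                continue
            mass = counts[node] * mass_per_packet
            p0 = tree.node_pos[tree.parent(node)]
            p1 = tree.node_pos[node]
            length = np.linalg.norm(p1 - p0)
            n_pts = max(2, int(np.ceil(length / spacing.min())) + 1)
            pts = p0 + (p1 - p0) * np.linspace(0, 1, n_pts)[:, None]
            ijk = np.rint((pts - np.asarray(tree.origin)) / spacing).astype(int)
            ijk = np.clip(ijk, 0, np.asarray(shape) - 1)
            np.add.at(grid, (ijk[:, 0], ijk[:, 1], ijk[:, 2]), mass / n_pts)
        if blur_sigma_vox > 0:
            grid = ndimage.gaussian_filter(grid, sigma=blur_sigma_vox, mode="constant")
        grid[label_map.labels != lobe] = 0.0
        s = grid.sum()
        if s > 0:
            out += grid * (lobe_mass / s)
    return out


def simulate_deposition(
    label_map: LobeLabelMap,
    trees: dict[int, ArterialTree],
    schedule: FractionSchedule,
    condition: FlowCondition,
    spheres: MicrosphereSpec = MicrosphereSpec(),
    seed: int = 0,
    lobe_perfusion: np.ndarray | None = None,
    n_packets_per_fraction: int = 10_000,
    gamma: float = 3.0,
    lam: float = 0.25,
    tau_g: float = 2.0,
    blur_sigma_vox: float = 1.0,
    capacity_packets_per_mm3: float | None = None,
    rasterise: bool = True,
) -> PhantomTruth:
    """Simulate microsphere administration over a fraction schedule.

    Parameters
    ----------
    lobe_perfusion : (5,) float, optional
        Ground-truth lobe flow shares; defaults to volume-proportional
        shares with seeded jitter.
    n_packets_per_fraction : int
        Packet granularity; a 250 mg fraction is ~1.26e7 spheres, far
        beyond per-sphere need — packet-scale binomial noise already
        dominates voxel statistics.
    gamma, lam, tau_g
        Streamline-bias exponent, lodging amplitude and generation scale of
        the lodging law (see module docstring).
    capacity_packets_per_mm3 : float, optional
        Per-segment packet capacity per mm^3 of lumen (capacity scales with
        radius^3 for roughly length-proportional segments).  ``None``
        disables the limit (the default; study doses never saturate).
    rasterise : bool
        Build the cumulative concentration maps (disable for transport-only
        studies).
    """
    if set(trees) != {1, 2, 3, 4, 5}:
        raise ValueError("trees must cover all 5 lobes")
    if lobe_perfusion is None:
        lobe_perfusion = lobe_perfusion_fractions(label_map, seed=seed)
    lobe_perfusion = np.asarray(lobe_perfusion, dtype=float)
    lobe_perfusion = lobe_perfusion / lobe_perfusion.sum()

    rng = substream(seed, "deposition")
    mixing = condition.mixing
    p_lobe = _biased_split(lobe_perfusion, mixing, gamma)

    # segment index bookkeeping (concatenated lobe-by-lobe; node 0 of each
    # tree is the inlet and carries no mass)
    seg_lobe, seg_node, seg_gen = [], [], []
    offsets = {}
    for lobe in range(1, 6):
        tree = trees[lobe]
        offsets[lobe] = len(seg_lobe)
        for node in range(tree.n_nodes):
            seg_lobe.append(lobe)
            seg_node.append(node)
            seg_gen.append(tree.generation[node])
    seg_lobe = np.asarray(seg_lobe)
    seg_node = np.asarray(seg_node)
    seg_gen = np.asarray(seg_gen)

    n_frac = schedule.n_fractions
    deposited = np.zeros((n_frac, seg_lobe.size))
    territory_idx = {lobe: _territory_index(trees[lobe]) for lobe in trees}
    conc_maps: list[VolumeGrid] = []
    cumulative = np.zeros(label_map.shape)
    voxel_ml = label_map.voxel_volume_ml

    caps = None
    if capacity_packets_per_mm3 is not None:
        caps = {}
        for lobe, tree in trees.items():
            seg_len = np.array(
                [tree.segment_length_mm(n) for n in range(tree.n_nodes)]
            )
            lumen_mm3 = np.pi * tree.radius**2 * np.maximum(seg_len, tree.radius)
            caps[lobe] = np.maximum(
                1, (capacity_packets_per_mm3 * lumen_mm3)
            ).astype(np.int64)

    # A packet stands for a fixed number of spheres: the count scales with
    # fraction mass (n_packets_per_fraction refers to the first fraction).
    ref_mass = schedule.delivered_masses_mg[0]
    for k, mass in enumerate(schedule.delivered_masses_mg):
        n_packets = max(1, int(round(n_packets_per_fraction * mass / ref_mass)))
        mass_per_packet = mass / n_packets
        lobe_counts = rng.multinomial(n_packets, p_lobe)
        counts_by_lobe = {}
        for lobe in range(1, 6):
            tree = trees[lobe]
            counts = _route_lobe_packets(
                tree, int(lobe_counts[lobe - 1]), mixing, gamma, lam, tau_g, rng
            )
            if caps is not None:
                counts = _apply_capacity(counts, caps[lobe], tree.generations)
            counts_by_lobe[lobe] = counts
            deposited[k, offsets[lobe] : offsets[lobe] + tree.n_nodes] = (
                counts * mass_per_packet
            )
        if rasterise:
            cumulative = cumulative + _rasterise_fraction(
                trees, counts_by_lobe, mass_per_packet, label_map,
                blur_sigma_vox, territory_idx, rng,
            )
            conc_maps.append(
                VolumeGrid(
                    values=cumulative / voxel_ml,
                    spacing=label_map.spacing,
                    origin=label_map.origin,
                    mask=label_map.liver_mask,
                    role="concentration",
                )
            )

    return PhantomTruth(
        label_map=label_map,
        trees=trees,
        lobe_perfusion_fraction=lobe_perfusion,
        schedule=schedule,
        condition=condition,
        spheres=spheres,
        deposited_mass=deposited,
        segment_lobe=seg_lobe,
        segment_node=seg_node,
        segment_generation=seg_gen,
        true_concentration=conc_maps,
    )
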