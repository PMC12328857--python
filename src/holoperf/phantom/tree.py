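"""Synthetic arterial trees.

Each lobe receives a space-filling complete binary tree grown by recursive
2-means splitting of the lobe's voxel cloud.  Branch flow fractions are the
voxel-count shares of the two daughter sub-clouds (flow proportional to the
tissue volume served), and radii follow Murray's law: with branch fractions
f1 + f2 = 1 the daughter radii are r_child = r_parent * f_child^(1/3), so
r_parent^3 = sum r_child^3 exactly.  Terminal territories are the
nearest-terminal (Euclidean) partition of the lobe mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ..seeding import substream

__all__ = ["ArterialTree", "grow_arterial_tree"]


@dataclass
class ArterialTree:
    """Complete binary tree on a heap layout.

    Nodes are indexed 0..2^g - 2 for ``generations`` = g levels; node 0 is
    the lobe root (inlet).  The segment *into* node i (i >= 1) connects node
    (i - 1) // 2 to node i; there is no segment into the root.  Arrays below
    are indexed by node, with index 0 describing the (virtual) inlet.

    Attributes
    ----------
    node_pos : (n_nodes, 3) float
        Node positions, mm.
    radius : (n_nodes,) float
        Radius of the segment ending at each node (index 0: inlet radius), mm.
    flow_fraction : (n_nodes,) float
        Fraction of the lobe flow carried by the segment into each node
        (index 0: 1.0).
    generation : (n_nodes,) int
        Segment generation = tree level of the child node (root segments
        are generation 1; index 0 is 0).
    territory_voxels : (N, 3) int
        Voxel indices of the lobe mask.
    territory_terminal : (N,) int
        For each lobe voxel, the node index of its nearest terminal.
    spacing : 3-tuple
        Voxel spacing of the underlying grid, mm.
    """

    generations: int
    node_pos: np.ndarray
    radius: np.ndarray
    flow_fraction: np.ndarray
    generation: np.ndarray
    territory_voxels: np.ndarray
    territory_terminal: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def n_nodes(self) -> int:
        return self.node_pos.shape[0]

    @property
    def n_segments(self) -> int:
        return self.n_nodes - 1

    @property
    def first_terminal(self) -> int:
        """Node index of the first terminal segment (leaf nodes)."""
        return 2 ** (self.generations - 1) - 1

    @property
    def terminal_nodes(self) -> np.ndarray:
        return np.arange(self.first_terminal, self.n_nodes)

    @property
    def n_terminals(self) -> int:
        return self.n_nodes - self.first_terminal

    def is_terminal(self, node: int) -> bool:
        return node >= self.first_terminal

    def children(self, node: int) -> tuple[int, int]:
        return 2 * node + 1, 2 * node + 2

    def parent(self, node: int) -> int:
        return (node - 1) // 2

    def branch_probabilities(self) -> np.ndarray:
        """P(left child) at each internal node (flow-proportional)."""
        n_int = self.first_terminal
        left = self.flow_fraction[2 * np.arange(n_int) + 1]
        parent = self.flow_fraction[np.arange(n_int)]
        return left / parent

    def territory_sizes(self) -> dict[int, int]:
        """Voxel count of each terminal's territory."""
        counts = np.bincount(self.territory_terminal, minlength=self.n_nodes)
        return {int(t): int(counts[t]) for t in self.terminal_nodes}

    def segment_length_mm(self, node: int) -> float:
        if node == 0:
            return 0.0
        return float(np.linalg.norm(self.node_pos[node] - self.node_pos[self.parent(node)]))


def _split_two(coords_mm: np.ndarray, rng: np.random.Generator):
    """Split a voxel cloud into two nonempty sub-clouds (2-means with a
    PCA-median fallback for degenerate cases)."""
    n = coords_mm.shape[0]
    if n < 2:
        raise ValueError("cannot split fewer than 2 voxels")
    # k-means with deterministic farthest-pair init
    c0 = coords_mm[rng.integers(n)]
    d = np.linalg.norm(coords_mm - c0, axis=1)
    c1 = coords_mm[int(np.argmax(d))]
    d1 = np.linalg.norm(coords_mm - c1, axis=1)
    c0 = coords_mm[int(np.argmax(d1))]
    centers = np.stack([c0, c1])
    assign = np.zeros(n, dtype=bool)
    for _ in range(12):
        dd = np.stack([np.linalg.norm(coords_mm - c, axis=1) for c in centers])
        new_assign = dd[1] < dd[0]
        if np.array_equal(new_assign, assign) and _ > 0:
            break
        assign = new_assign
        for k in (0, 1):
            sel = assign == bool(k)
            if sel.any():
                centers[k] = coords_mm[sel].mean(axis=0)
    if assign.all() or not assign.any():
        # degenerate: split at the median along the longest axis
        axis = int(np.argmax(coords_mm.max(0) - coords_mm.min(0)))
        med = np.median(coords_mm[:, axis])
        assign = coords_mm[:, axis] > med
        if assign.all() or not assign.any():
            assign = np.zeros(n, dtype=bool)
            assign[: n // 2] = True
    return ~assign, assign


def grow_arterial_tree(
    lobe_mask: np.ndarray,
    spacing,
    generations: int = 7,
    seed: int = 0,
    root_radius_mm: float = 1.5,
    calibre_noise: float = 0.30,
    origin=(0.0, 0.0, 0.0),
) -> ArterialTree:
    """Grow a complete binary arterial tree filling a lobe mask.

    Parameters
    ----------
    lobe_mask : 3-D bool array
        The lobe's voxels.
    generations : int
        Number of node levels (>= 2).  A complete tree has
        2^(generations - 1) terminal segments.  If the mask cannot host one
        voxel per terminal the depth is reduced with a warning.
    root_radius_mm : float
        Radius of the lobe inlet; daughter radii follow Murray's law.
    calibre_noise : float
        Lognormal SD of the branch flow-ratio perturbation.  Real vessel
        calibres are not set by served tissue volume alone; this makes
        terminal flow deviate from territory volume, the residual dose
        heterogeneity seen even under well-mixed administration.  0 gives
        purely volume-proportional flow.
    """
    if generations < 2:
        raise ValueError("generations must be >= 2")
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    spacing = tuple(float(s) for s in spacing)

    coords = np.argwhere(lobe_mask)
    n_vox = coords.shape[0]
    if n_vox < 2:
        raise ValueError("lobe mask too small to grow a tree")
    while 2 ** (generations - 1) > n_vox:
        generations -= 1
        warnings.warn(
            f"lobe mask too small for requested depth; reduced to "
            f"{generations} generations",
            stacklevel=2,
        )
    coords_mm = coords * np.asarray(spacing) + np.asarray(origin)

    rng = substream(seed, "tree")
    n_nodes = 2 ** generations - 1
    node_pos = np.zeros((n_nodes, 3))
    radius = np.zeros(n_nodes)
    flow = np.zeros(n_nodes)
    gen = np.zeros(n_nodes, dtype=int)

    node_pos[0] = coords_mm.mean(axis=0)
    radius[0] = float(root_radius_mm)
    flow[0] = 1.0

    # Recursive split, breadth-first over the heap.
    subsets: list[np.ndarray | None] = [None] * n_nodes
    subsets[0] = np.arange(n_vox)
    first_leaf = 2 ** (generations - 1) - 1
    for node in range(first_leaf):
        sel = subsets[node]
        if sel.size < 2:
            # degenerate deep split: both children share the single voxel
            left_sel = np.ones(sel.size, dtype=bool)
            right_sel = left_sel
        else:
            left_sel, right_sel = _split_two(coords_mm[sel], rng)
        # volume-proportional split, perturbed by calibre variability
        n_left = int(left_sel.sum())
        frac_left = 0.5 if sel.size < 2 else n_left / sel.size
        if calibre_noise > 0 and sel.size >= 2:
            odds = frac_left / (1.0 - frac_left)
            odds *= np.exp(calibre_noise * rng.standard_normal())
            frac_left = odds / (1.0 + odds)
        for side, child_sel, frac in (
            (0, left_sel, frac_left),
            (1, right_sel, 1.0 - frac_left),
        ):
            child = 2 * node + 1 + side
            child_idx = sel[child_sel]
            subsets[child] = child_idx
            flow[child] = flow[node] * frac
            radius[child] = radius[node] * frac ** (1.0 / 3.0)
            node_pos[child] = coords_mm[child_idx].mean(axis=0)
            gen[child] = gen[node] + 1
        subsets[node] = None  # free

    # Terminal territories: nearest-terminal partition of the lobe mask.
    terminals = np.arange(first_leaf, n_nodes)
    tree_kd = cKDTree(node_pos[terminals])
    _, nearest = tree_kd.query(coords_mm)
    territory_terminal = terminals[nearest]

    return ArterialTree(
        generations=generations,
        node_pos=node_pos,
        radius=radius,
        flow_fraction=flow,
        generation=gen,
        territory_voxels=coords,
        territory_terminal=territory_terminal,
        spacing=spacing,
        origin=tuple(float(o) for o in origin),
    )
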