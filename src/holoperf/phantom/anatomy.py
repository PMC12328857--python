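"""Synthetic five-lobe liver anatomy.

The phantom liver is a smooth blob (an ellipsoid perturbed by a low-frequency
Gaussian random field) partitioned into the five porcine lobes — left
lateral, left medial, right medial, right lateral, caudate — by a
multiplicatively weighted Voronoi tessellation whose weights are iterated
until the lobe volumes match the requested fractions.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..grids import LobeLabelMap
from ..seeding import substream

__all__ = ["build_liver_phantom", "DEFAULT_VOLUME_FRACTIONS"]

#: Default lobe volume fractions (left lateral, left medial, right medial,
#: right lateral, caudate).
DEFAULT_VOLUME_FRACTIONS = (0.30, 0.20, 0.20, 0.22, 0.08)


def _smooth_field(shape, rng, sigma_frac: float = 0.12) -> np.ndarray:
    """Zero-mean unit-SD smooth random field for organ-shape perturbation."""
    noise = rng.standard_normal(shape)
    sigma = [max(1.0, s * sigma_frac) for s in shape]
    field = ndimage.gaussian_filter(noise, sigma=sigma, mode="nearest")
    sd = field.std()
    return field / sd if sd > 0 else field


def build_liver_phantom(
    shape: tuple[int, int, int] = (96, 96, 64),
    spacing=2.0,
    volume_fractions=DEFAULT_VOLUME_FRACTIONS,
    target_volume_ml: float | None = None,
    seed: int = 0,
    perturbation: float = 0.25,
    min_voxels_per_lobe: int = 10,
) -> LobeLabelMap:
    """Build a five-lobe liver label map.

    Parameters
    ----------
    shape, spacing
        Lattice dimensions and voxel edge length (mm).  The defaults give a
        192 x 192 x 128 mm box; with the default target volume this hosts a
        full-scale organ of roughly 2,600 mL.  Tests use smaller grids
        (roughly 300 mL).
    volume_fractions
        Target lobe volume fractions, summing to 1.
    target_volume_ml
        Liver volume.  Defaults to 55% of the bounding box, which
        reproduces approximately 2,600 mL on the default grid.
    seed
        Seed for the organ shape and lobe seeds.
    perturbation
        Amplitude of the smooth random perturbation of the organ surface
        (relative to the ellipsoid level function).

    Raises
    ------
    ValueError
        If the grid is too small to host five lobes of at least
        ``min_voxels_per_lobe`` voxels.
    """
    shape = tuple(int(s) for s in shape)
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    spacing = tuple(float(s) for s in spacing)
    fractions = np.asarray(volume_fractions, dtype=float)
    if fractions.size != 5 or np.any(fractions <= 0):
        raise ValueError("volume_fractions must be 5 positive numbers")
    fractions = fractions / fractions.sum()

    voxel_ml = float(np.prod(spacing)) / 1000.0
    box_ml = float(np.prod(shape)) * voxel_ml
    if target_volume_ml is None:
        target_volume_ml = 0.55 * box_ml
    n_target = int(round(target_volume_ml / voxel_ml))
    n_target = min(n_target, int(0.9 * np.prod(shape)))
    if n_target < 5 * min_voxels_per_lobe:
        raise ValueError(
            f"shape too small to host 5 lobes: {n_target} liver voxels < "
            f"{5 * min_voxels_per_lobe}"
        )

    rng = substream(seed, "anatomy")

    # Ellipsoid level function, axes aligned with the grid.
    idx = np.indices(shape, dtype=float)
    center = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) * 0.45
    quad = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    level = quad - 1.0 + perturbation * _smooth_field(shape, rng)

    # Threshold at the quantile that yields exactly the target voxel count,
    # then keep the largest connected component.
    thresh = np.partition(level.ravel(), n_target - 1)[n_target - 1]
    mask = level <= thresh
    comp, n_comp = ndimage.label(mask)
    if n_comp > 1:
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n_comp + 1))
        mask = comp == (1 + int(np.argmax(sizes)))

    coords = np.argwhere(mask).astype(float)  # (N, 3) voxel indices
    n_vox = coords.shape[0]
    if n_vox < 5 * min_voxels_per_lobe:
        raise ValueError("shape too small to host 5 lobes after masking")
    coords_mm = coords * np.asarray(spacing)

    # Seed points: spread within the organ, deterministic given the seed.
    # k-means++-style farthest-point seeding from a random start.
    centers = np.empty((5, 3))
    centers[0] = coords_mm[rng.integers(n_vox)]
    d2 = np.sum((coords_mm - centers[0]) ** 2, axis=1)
    for k in range(1, 5):
        centers[k] = coords_mm[int(np.argmax(d2))]
        d2 = np.minimum(d2, np.sum((coords_mm - centers[k]) ** 2, axis=1))

    # Multiplicatively weighted Voronoi iteration: assign voxels to
    # argmin_i dist_i / w_i and push w_i toward the target volume shares.
    weights = np.ones(5)
    assign = np.zeros(n_vox, dtype=np.int8)
    for it in range(60):
        dists = np.stack(
            [np.linalg.norm(coords_mm - centers[k], axis=1) for k in range(5)]
        )
        assign = np.argmin(dists / weights[:, None], axis=0)
        counts = np.bincount(assign, minlength=5).astype(float)
        shares = counts / n_vox
        if np.all(counts > 0) and np.max(np.abs(shares - fractions) / fractions) < 0.02:
            break
        ratio = fractions / np.maximum(shares, 1e-6)
        weights *= ratio ** 0.35
        weights /= weights.prod() ** (1 / 5)
        if it % 10 == 9:  # re-center occasionally to keep lobes compact
            for k in range(5):
                if counts[k] > 0:
                    centers[k] = coords_mm[assign == k].mean(axis=0)

    counts = np.bincount(assign, minlength=5)
    if np.any(counts < min_voxels_per_lobe):
        raise ValueError(
            f"shape too small to host 5 lobes: lobe voxel counts {counts.tolist()}"
        )

    labels = np.zeros(shape, dtype=np.int16)
    ci = coords.astype(int)
    labels[ci[:, 0], ci[:, 1], ci[:, 2]] = assign + 1
    return LobeLabelMap(labels=labels, spacing=spacing)
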