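"""Shared volumetric containers.

Every stage of the pipeline exchanges data as :class:`VolumeGrid` objects —
3-D scalar fields on a regular lattice with voxel spacing in mm — or as thin
stacks of them (:class:`MultiEchoSeries`, :class:`DynamicSeries`).  Axis
order is (x, y, z), indexing is 0-based, and coordinates refer to voxel
centers: the physical position of voxel (i, j, k) is
``origin + (i, j, k) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "VolumeGrid",
    "LobeLabelMap",
    "MultiEchoSeries",
    "DynamicSeries",
    "LOBE_NAMES",
    "FormatError",
    "DomainError",
]

#: Porcine liver lobe labels used throughout: label -> anatomical name.
LOBE_NAMES = {
    1: "left lateral",
    2: "left medial",
    3: "right medial",
    4: "right lateral",
    5: "caudate",
}


class FormatError(ValueError):
    """Raised when an on-disk volume or sidecar violates the expected layout."""


class DomainError(ValueError):
    """Raised when an input value is outside the physical domain of an operation."""


def _as_spacing(spacing) -> tuple[float, float, float]:
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise FormatError(f"spacing must have 3 entries, got {len(spacing)}")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise FormatError(f"spacing must be positive and finite, got {spacing}")
    return spacing


@dataclass
class VolumeGrid:
    """A 3-D scalar field with physical geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values.  The physical unit depends on ``role`` (signal a.u.,
        Gy, mg/mL, s^-1, HU, ...).
    spacing : float or 3-sequence
        Voxel edge lengths in mm, all strictly positive.
    origin : 3-sequence
        Physical position of voxel (0, 0, 0) in mm.
    mask : ndarray of bool, optional
        Region of interest with the same shape as ``values``.
    role : str
        Free-text unit/provenance tag ("signal", "dose", "concentration",
        "hu", ...).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mask: np.ndarray | None = None
    role: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise FormatError(
                f"expected 3-D volume, got {self.values.ndim}-D payload"
            )
        self.spacing = _as_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.origin) != 3:
            raise FormatError("origin must have 3 entries")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise FormatError(
                    f"mask shape {self.mask.shape} != values shape {self.values.shape}"
                )

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> mm affine (diagonal; phantom series are axis-aligned)."""
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def masked(self) -> np.ndarray:
        """Values inside the mask (all values when no mask is set)."""
        if self.mask is None:
            return self.values.ravel()
        return self.values[self.mask]

    def with_values(self, values: np.ndarray, role: str | None = None) -> "VolumeGrid":
        """A new grid sharing this grid's geometry and mask."""
        return VolumeGrid(
            values=values,
            spacing=self.spacing,
            origin=self.origin,
            mask=None if self.mask is None else self.mask.copy(),
            role=self.role if role is None else role,
        )

    def same_geometry(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class LobeLabelMap:
    """Integer label volume: 0 = background, 1-5 = liver lobes.

    The five porcine lobes follow the fixed convention in :data:`LOBE_NAMES`
    (1 left lateral ... 5 caudate).  Every lobe must be nonempty and labels
    outside {0..5} are rejected.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    names: dict[int, str] = field(default_factory=lambda: dict(LOBE_NAMES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError("label map must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.rint(self.labels).astype(np.int16)
            if not np.allclose(lab, self.labels):
                raise FormatError("label map must be integer-valued")
            self.labels = lab
        self.spacing = _as_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        present = set(np.unique(self.labels).tolist())
        if not present <= {0, 1, 2, 3, 4, 5}:
            raise FormatError(f"labels outside 0..5 present: {sorted(present - set(range(6)))}")
        missing = [l for l in range(1, 6) if l not in present]
        if missing:
            raise FormatError(f"empty lobe label(s): {missing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def liver_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def lobe_mask(self, lobe: int) -> np.ndarray:
        if lobe not in range(1, 6):
            raise ValueError(f"lobe must be 1..5, got {lobe}")
        return self.labels == lobe

    def lobe_volumes_ml(self) -> np.ndarray:
        """Volume of lobes 1..5 in mL."""
        counts = np.bincount(self.labels.ravel(), minlength=6)[1:6]
        return counts * self.voxel_volume_ml

    def liver_volume_ml(self) -> float:
        return float(np.count_nonzero(self.labels)) * self.voxel_volume_ml

    def as_grid(self) -> VolumeGrid:
        return VolumeGrid(
            values=self.labels,
            spacing=self.spacing,
            origin=self.origin,
            role="labels",
        )


@dataclass
class MultiEchoSeries:
    """Echo-resolved stack of magnitude images from a multi-echo gradient echo.

    The default acquisition mirrors the T2*-weighted holmium-sensitive
    protocol: 10 echoes, TE1 = 1.7 ms, deltaTE = 1.35 ms.
    """

    echoes: list[VolumeGrid]
    echo_times_ms: np.ndarray

    def __post_init__(self) -> None:
        self.echo_times_ms = np.asarray(self.echo_times_ms, dtype=float)
        if self.echo_times_ms.ndim != 1:
            raise FormatError("echo_times_ms must be a 1-D sequence")
        if len(self.echoes) != self.echo_times_ms.size:
            raise FormatError(
                f"echo count mismatch: {len(self.echoes)} volumes vs "
                f"{self.echo_times_ms.size} echo times"
            )
        if np.any(np.diff(self.echo_times_ms) <= 0):
            raise FormatError("echo times must be strictly increasing")
        first = self.echoes[0]
        for e in self.echoes[1:]:
            if not first.same_geometry(e):
                raise FormatError("all echoes must share shape, spacing and origin")

    @classmethod
    def from_array(
        cls,
        data_4d: np.ndarray,
        echo_times_ms: Sequence[float],
        spacing=(1.0, 1.0, 1.0),
        origin=(0.0, 0.0, 0.0),
        mask: np.ndarray | None = None,
    ) -> "MultiEchoSeries":
        data_4d = np.asarray(data_4d)
        if data_4d.ndim != 4:
            raise FormatError("expected 4-D array (x, y, z, echo)")
        echoes = [
            VolumeGrid(data_4d[..., i], spacing=spacing, origin=origin, mask=mask,
                       role="signal")
            for i in range(data_4d.shape[-1])
        ]
        return cls(echoes=echoes, echo_times_ms=np.asarray(echo_times_ms, float))

    @property
    def n_echoes(self) -> int:
        return len(self.echoes)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.echoes[0].shape

    @property
    def spacing(self):
        return self.echoes[0].spacing

    def data(self) -> np.ndarray:
        """Stack to (nx, ny, nz, n_echoes)."""
        return np.stack([e.values for e in self.echoes], axis=-1)


def default_echo_times(n_echoes: int = 10, te1_ms: float = 1.7,
                       delta_te_ms: float = 1.35) -> np.ndarray:
    """TE_k = TE1 + k * deltaTE for k = 0..n-1 (default 1.7 + 1.35 k ms)."""
    return te1_ms + delta_te_ms * np.arange(n_echoes)


@dataclass
class DynamicSeries:
    """Time-resolved stack of signal volumes from a dynamic contrast scan.

    Default acquisition: 200 frames at 0.86 s intervals; the series duration
    (time from first to last frame) is then (200 - 1) * 0.86 = 171.14 s.
    """

    frames: list[VolumeGrid]
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.frame_interval_s = float(self.frame_interval_s)
        if self.frame_interval_s <= 0:
            raise FormatError("frame_interval_s must be > 0")
        if not self.frames:
            raise FormatError("dynamic series needs at least one frame")
        first = self.frames[0]
        for f in self.frames[1:]:
            if not first.same_geometry(f):
                raise FormatError("all frames must share shape, spacing and origin")

    @classmethod
    def from_array(
        cls,
        data_4d: np.ndarray,
        frame_interval_s: float,
        spacing=(1.0, 1.0, 1.0),
        origin=(0.0, 0.0, 0.0),
    ) -> "DynamicSeries":
        data_4d = np.asarray(data_4d)
        if data_4d.ndim != 4:
            raise FormatError("expected 4-D array (x, y, z, t)")
        frames = [
            VolumeGrid(data_4d[..., i], spacing=spacing, origin=origin, role="signal")
            for i in range(data_4d.shape[-1])
        ]
        return cls(frames=frames, frame_interval_s=frame_interval_s)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames[0].shape

    @property
    def times_s(self) -> np.ndarray:
        return self.frame_interval_s * np.arange(self.n_frames)

    @property
    def duration_s(self) -> float:
        """Time of the last frame relative to the first."""
        return self.frame_interval_s * (self.n_frames - 1)

    def data(self) -> np.ndarray:
        """Stack to (nx, ny, nz, n_frames)."""
        return np.stack([f.values for f in self.frames], axis=-1)
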