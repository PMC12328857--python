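"""NIfTI readers and writers.

Volumes travel as NIfTI-1 files; echo-resolved and time-resolved series as
4-D NIfTI plus a JSON sidecar carrying the timing metadata (NIfTI has no
standard field for multi-echo timing).  The sidecar shares the image path
with the extension replaced by ``.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import (
    DynamicSeries,
    FormatError,
    MultiEchoSeries,
    VolumeGrid,
    LobeLabelMap,
)

__all__ = [
    "read_volume",
    "write_volume",
    "read_label_map",
    "write_label_map",
    "read_multiecho",
    "write_multiecho",
    "read_dynamic",
    "write_dynamic",
    "sidecar_path",
]


def _load(path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    return nib.load(str(path))


def _geometry(img: nib.Nifti1Image):
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise FormatError(f"non-positive spacing in header: spacing={zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return tuple(float(z) for z in zooms), origin


def read_volume(path, role: str = "") -> VolumeGrid:
    """Read a 3-D NIfTI volume.

    Raises
    ------
    FileNotFoundError
        If the file is missing.
    FormatError
        For a non-3-D payload or non-positive header spacing.
    """
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(
        s == 1 for s in data.shape[3:]
    ) else data
    if data.ndim != 3:
        raise FormatError(
            f"expected 3-D volume, got {data.ndim}-D payload in {path}"
        )
    spacing, origin = _geometry(img)
    return VolumeGrid(values=np.asarray(data, dtype=np.float64), spacing=spacing,
                      origin=origin, role=role)


def write_volume(grid: VolumeGrid, path, dtype=np.float32) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(grid.values, dtype=dtype), grid.affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))
    return path


def read_label_map(path) -> LobeLabelMap:
    grid = read_volume(path, role="labels")
    return LobeLabelMap(labels=np.rint(grid.values).astype(np.int16),
                        spacing=grid.spacing, origin=grid.origin)


def write_label_map(labels: LobeLabelMap, path) -> Path:
    return write_volume(labels.as_grid(), path, dtype=np.int16)


def sidecar_path(path) -> Path:
    """JSON sidecar path for a NIfTI file (``x.nii``/``x.nii.gz`` -> ``x.json``)."""
    path = Path(path)
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + ".json")
    return path.with_suffix(".json")


def _read_4d(path) -> tuple[np.ndarray, tuple, tuple]:
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(f"expected 4-D series, got {data.ndim}-D payload in {path}")
    spacing, origin = _geometry(img)
    return np.asarray(data, dtype=np.float64), spacing, origin


def read_multiecho(path_4d, sidecar=None) -> MultiEchoSeries:
    """Read a 4-D multi-echo magnitude series with its echo-time sidecar.

    The sidecar JSON must contain ``echo_times_ms`` with exactly one entry
    per 4th-dimension volume, strictly increasing.
    """
    data, spacing, origin = _read_4d(path_4d)
    sidecar = Path(sidecar) if sidecar is not None else sidecar_path(path_4d)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing echo-time sidecar: {sidecar}")
    meta = json.loads(sidecar.read_text())
    tes = np.asarray(meta.get("echo_times_ms", []), dtype=float)
    if tes.size != data.shape[-1]:
        raise FormatError(
            f"echo count mismatch: {data.shape[-1]} volumes vs {tes.size} echo times"
        )
    return MultiEchoSeries.from_array(data, tes, spacing=spacing, origin=origin)


def write_multiecho(series: MultiEchoSeries, path_4d, dtype=np.float32) -> Path:
    path_4d = Path(path_4d)
    path_4d.parent.mkdir(parents=True, exist_ok=True)
    grid0 = series.echoes[0]
    img = nib.Nifti1Image(np.asarray(series.data(), dtype=dtype), grid0.affine)
    nib.save(img, str(path_4d))
    sidecar_path(path_4d).write_text(
        json.dumps({"echo_times_ms": series.echo_times_ms.tolist()}, indent=2)
    )
    return path_4d


def read_dynamic(path_4d, sidecar=None) -> DynamicSeries:
    """Read a 4-D dynamic contrast series with its frame-interval sidecar."""
    data, spacing, origin = _read_4d(path_4d)
    sidecar = Path(sidecar) if sidecar is not None else sidecar_path(path_4d)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing frame-interval sidecar: {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "frame_interval_s" not in meta:
        raise FormatError(f"sidecar lacks frame_interval_s: {sidecar}")
    return DynamicSeries.from_array(
        data, float(meta["frame_interval_s"]), spacing=spacing, origin=origin
    )


def write_dynamic(series: DynamicSeries, path_4d, dtype=np.float32) -> Path:
    path_4d = Path(path_4d)
    path_4d.parent.mkdir(parents=True, exist_ok=True)
    grid0 = series.frames[0]
    img = nib.Nifti1Image(np.asarray(series.data(), dtype=dtype), grid0.affine)
    nib.save(img, str(path_4d))
    sidecar_path(path_4d).write_text(
        json.dumps({"frame_interval_s": series.frame_interval_s,
                    "n_frames": series.n_frames}, indent=2)
    )
    return path_4d
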