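"""NIfTI input/output and the in-memory containers used across the package.

Coordinate contract
-------------------
Voxel indices are 0-based.  The world coordinate (in mm) of voxel
``(i, j, k)`` is ``origin + (i, j, k) * spacing``, axis by axis; all
registration math operates in world millimetres.  Images read from disk
keep the header spacing and the affine translation as ``origin``; any
rotational part of a file's affine is ignored (volumes are treated as
axis-aligned grids), which is the convention every other module relies on.

Intensities are cast to floating point on load.  If a file contains
negative values they are shifted so the minimum becomes zero, because the
intensity-weighted moments downstream assume non-negative mass; the shift
is logged.  2-D single-slice files are promoted to shape ``(X, Y, 1)`` so
a single code path serves both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Volume",
    "SeriesVolume",
    "LabelMap",
    "read_volume",
    "write_volume",
    "read_series",
    "write_series",
    "read_labels",
    "write_labels",
]


@dataclass
class Volume:
    """A 3-D scalar intensity grid with voxel spacing and world origin.

    Parameters
    ----------
    data:
        3-D array of finite intensities (arbitrary units).
    spacing:
        Per-axis voxel size in mm, strictly positive.
    origin:
        World coordinate of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume contains non-finite intensities")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if len(self.origin) != 3:
            raise ValueError("origin must have 3 components")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing, self.origin)

    def world_affine(self) -> np.ndarray:
        """4x4 affine mapping voxel index -> world mm."""
        a = np.eye(4)
        a[:3, :3] = np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a


@dataclass
class SeriesVolume:
    """A 4-D (x, y, z, t) time-series grid with repetition time in seconds."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tr: float = 2.5
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"SeriesVolume data must be 4-D, got ndim={self.data.ndim}")
        if self.data.shape[3] < 2:
            raise ValueError("time series needs at least 2 time points")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("SeriesVolume contains non-finite values")
        self.tr = float(self.tr)
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class LabelMap:
    """Integer ROI labels on a 3-D grid: 0 = background, k>0 = ROI k."""

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValueError("LabelMap must be 3-D")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise ValueError("label map contains non-integer values")
            arr = arr.astype(np.int32)
        if arr.min() < 0:
            raise ValueError("label map contains negative labels")
        self.labels = arr
        present = set(int(k) for k in np.unique(arr) if k > 0)
        if not self.names:
            self.names = {k: f"ROI{k}" for k in sorted(present)}
        else:
            missing = set(self.names) - present
            if missing:
                raise ValueError(f"named labels absent from grid: {sorted(missing)}")

    @property
    def rois(self) -> list[int]:
        return sorted(self.names)


def _load(path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    return nib.load(str(path))


def read_volume(path) -> Volume:
    """Read a 3-D NIfTI file as a :class:`Volume`.

    2-D single-slice images are promoted to shape ``(X, Y, 1)``; negative
    intensities are shifted to zero minimum (logged).
    """
    img = _load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 2:
        data = data[:, :, np.newaxis]
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[:, :, :, 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got {data.ndim} dimensions")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: image contains non-finite voxels")
    if data.min() < 0:
        shift = -float(data.min())
        logger.warning("%s: shifting intensities by +%g to make them non-negative", path, shift)
        data = data + shift
    zooms = img.header.get_zooms()
    spacing = tuple(float(z) for z in zooms[:3])
    if len(spacing) < 3:
        spacing = spacing + (1.0,) * (3 - len(spacing))
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return Volume(data, spacing, origin)


def write_volume(v: Volume, path) -> None:
    """Write a :class:`Volume` to NIfTI (float32 storage)."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    affine = v.world_affine()
    img = nib.Nifti1Image(v.data.astype(np.float32), affine)
    img.header.set_zooms(v.spacing)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_series(path) -> SeriesVolume:
    """Read a 4-D NIfTI resting-state series; TR is taken from the header.

    Header time units of msec/usec are converted to seconds.
    """
    img = _load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D series, got {data.ndim} dimensions")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: series contains non-finite voxels")
    zooms = img.header.get_zooms()
    spacing = tuple(float(z) for z in zooms[:3])
    tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    _, t_unit = img.header.get_xyzt_units()
    if t_unit == "msec":
        tr /= 1e3
    elif t_unit == "usec":
        tr /= 1e6
    if tr <= 0:
        raise ValueError(f"{path}: header does not define a positive repetition time")
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return SeriesVolume(data, spacing, tr, origin)


def write_series(s: SeriesVolume, path) -> None:
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    affine = np.eye(4)
    affine[:3, :3] = np.diag(s.spacing)
    affine[:3, 3] = s.origin
    img = nib.Nifti1Image(s.data.astype(np.float32), affine)
    img.header.set_zooms(s.spacing + (s.tr,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_labels(path, names: dict[int, str] | None = None) -> LabelMap:
    """Read an integer ROI label map; float-valued files are rejected."""
    img = _load(path)
    data = np.asarray(img.dataobj)
    if data.ndim == 2:
        data = data[:, :, np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D label map, got {data.ndim} dimensions")
    if not np.issubdtype(data.dtype, np.integer):
        if not np.all(np.isfinite(data)) or not np.all(data == np.round(data)):
            raise ValueError(f"{path}: label map contains non-integer values")
        data = data.astype(np.int32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return LabelMap(data, names or {}, spacing, origin)


def write_labels(m: LabelMap, path) -> None:
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    affine = np.eye(4)
    affine[:3, :3] = np.diag(m.spacing)
    affine[:3, 3] = m.origin
    img = nib.Nifti1Image(m.labels.astype(np.int16), affine)
    img.header.set_zooms(m.spacing)
    nib.save(img, str(path))
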