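"""Scalar image-similarity measures: MSE, NCC and mutual information.

All metrics are evaluated only over the overlap of the two images'
nonzero support (the field-of-view mask), so that zero padding produced
by resampling does not reward truncating one image out of the frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import Volume

__all__ = ["MetricValue", "mse", "ncc", "mutual_information", "overlap_mask"]


@dataclass(frozen=True)
class MetricValue:
    name: str
    value: float
    overlap_voxels: int


def _as_array(v) -> np.ndarray:
    if isinstance(v, Volume):
        return v.data
    return np.asarray(v, dtype=float)


def overlap_mask(a, b) -> np.ndarray:
    """Boolean mask of voxels inside both images' nonzero support."""
    a, b = _as_array(a), _as_array(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return (a != 0) & (b != 0)


def _masked(a, b, mask=None):
    a, b = _as_array(a), _as_array(b)
    if mask is None:
        mask = overlap_mask(a, b)
    if not mask.any():
        raise ValueError("empty overlap between image supports")
    return a[mask], b[mask], int(mask.sum())


def mse(a, b, mask=None) -> MetricValue:
    """Mean squared intensity difference over the overlap (lower is better)."""
    x, y, n = _masked(a, b, mask)
    return MetricValue("mse", float(np.mean((x - y) ** 2)), n)


def ncc(a, b, mask=None) -> MetricValue:
    """Pearson correlation of overlapping intensities, in [-1, 1]."""
    x, y, n = _masked(a, b, mask)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("NCC undefined: constant image over the overlap")
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return MetricValue("ncc", float(np.clip(r, -1.0, 1.0)), n)


def mutual_information(a, b, bins: int = 32, mask=None) -> MetricValue:
    """Joint-histogram mutual information in bits over the overlap."""
    x, y, n = _masked(a, b, mask)
    hist, _, _ = np.histogram2d(x, y, bins=bins)
    p = hist / hist.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    mi = float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))
    return MetricValue("mi", max(mi, 0.0), n)


_METRICS = {"mse": mse, "ncc": ncc, "mi": mutual_information}


def get_metric(name: str):
    """Look up a metric function by name ('mse' | 'ncc' | 'mi')."""
    try:
        return _METRICS[name]
    except KeyError:
        raise ValueError(f"unknown metric {name!r}; choose from {sorted(_METRICS)}") from None


def metric_sign(name: str) -> float:
    """+1 when larger is better (ncc, mi), -1 for mse."""
    if name == "mse":
        return -1.0
    if name in ("ncc", "mi"):
        return 1.0
    raise ValueError(f"unknown metric {name!r}")
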