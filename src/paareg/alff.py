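"""Amplitude of low-frequency fluctuation (ALFF) from 4-D BOLD series.

Per voxel the time course is linearly detrended, Fourier-transformed,
and the single-sided amplitude spectrum averaged over the frequency bins
inside the analysis band (default 0.01–0.08 Hz, the field-standard
resting-state band).  The spectrum is scaled so a unit-amplitude
sinusoid at an exact frequency bin yields amplitude 1, which makes ALFF
linear in signal amplitude.  The only preprocessing applied is the
detrend; slice timing, motion correction, smoothing and nuisance
regression are deliberately out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .volume_io import LabelMap, SeriesVolume

__all__ = ["ALFFMap", "DEFAULT_BAND", "detrend", "compute_alff", "roi_mean", "normalize_malff"]

DEFAULT_BAND = (0.01, 0.08)


@dataclass
class ALFFMap:
    """3-D grid of non-negative low-frequency amplitudes."""

    values: np.ndarray
    band: tuple[float, float]
    tr: float
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("ALFFMap values must be 3-D")
        if np.any(self.values < 0):
            raise ValueError("ALFF values must be non-negative")


def detrend(series: np.ndarray) -> np.ndarray:
    """Remove the best-fit line from a 1-D signal (residual mean is 0)."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("detrend expects a 1-D signal")
    if series.size < 3:
        raise ValueError("detrend needs at least 3 time points")
    return signal.detrend(series, type="linear")


def _band_bins(n_t: int, tr: float, band) -> tuple[np.ndarray, np.ndarray]:
    low, high = (float(b) for b in band)
    nyquist = 1.0 / (2.0 * tr)
    if not (0.0 < low < high <= nyquist + 1e-12):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high <= Nyquist ({nyquist:g} Hz)"
        )
    freqs = np.fft.rfftfreq(n_t, d=tr)
    inband = (freqs >= low - 1e-12) & (freqs <= high + 1e-12)
    if not inband.any():
        raise ValueError("no frequency bins fall inside the band; series too short")
    return freqs, inband


def compute_alff(s: SeriesVolume, band=DEFAULT_BAND) -> ALFFMap:
    """Voxelwise ALFF: mean in-band single-sided spectral amplitude.

    Deterministic.  Warns for short series (< 32 time points) where the
    band holds very few bins.
    """
    n_t = s.n_timepoints
    if n_t < 32:
        warnings.warn(f"only {n_t} time points; ALFF estimates will be coarse", stacklevel=2)
    _, inband = _band_bins(n_t, s.tr, band)
    data = signal.detrend(s.data, axis=-1, type="linear")
    spec = np.fft.rfft(data, axis=-1)
    amp = np.abs(spec) * (2.0 / n_t)
    amp[..., 0] /= 2.0
    if n_t % 2 == 0:
        amp[..., -1] /= 2.0
    values = amp[..., inband].mean(axis=-1)
    return ALFFMap(values, tuple(band), s.tr, s.spacing, s.origin)


def roi_mean(m: ALFFMap, labels: LabelMap, subject_id: str = "S0") -> pd.DataFrame:
    """Mean ALFF per ROI for one subject.

    Returns a tidy frame with columns subject_id, region, mean_alff.
    """
    if m.values.shape != labels.labels.shape:
        raise ValueError(
            f"grid mismatch: ALFF {m.values.shape} vs labels {labels.labels.shape}"
        )
    rows = []
    for k in labels.rois:
        mask = labels.labels == k
        if not mask.any():
            raise ValueError(f"label {k} is empty")
        rows.append(
            {"subject_id": subject_id, "region": labels.names[k],
             "mean_alff": float(m.values[mask].mean())}
        )
    return pd.DataFrame(rows)


def normalize_malff(m: ALFFMap, mask: LabelMap) -> ALFFMap:
    """Divide by the global in-mask mean (mALFF); in-mask mean becomes 1."""
    inside = mask.labels > 0
    if not inside.any():
        raise ValueError("mask is empty")
    mean = float(m.values[inside].mean())
    if mean <= 0:
        raise ValueError("in-mask mean ALFF is zero; cannot normalize")
    return ALFFMap(m.values / mean, m.band, m.tr, m.spacing, m.origin)
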