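"""Synthetic inputs with known ground truth.

Three families of generators cover the package's test surface:

* grayscale 3-D phantoms under known rigid motion with additive noise,
  for registration-recovery experiments.  The standard registration
  phantom is deliberately asymmetric (a sum of three anisotropic
  Gaussians with distinct covariances) because principal-axis
  registration is unidentifiable on symmetric objects; the sphere and
  cube kinds exist to exercise the degeneracy path;
* 4-D BOLD-like series in which each ROI carries a sinusoid of known
  amplitude at a region-specific low-band frequency (snapped to an exact
  FFT bin so spectral leakage does not distort amplitude ratios), plus
  optional white noise and linear drift;
* two-group cohorts (patients EG vs controls CG, default n = 107/51)
  with region-wise standardized ALFF effects and a 0-30 cognitive score
  correlated with specific regions through a Gaussian copula.

Every generator is bit-reproducible given its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .group_stats import DEFAULT_REGIONS, CohortRecord
from .paa_registration import compute_centroid
from .rigid_transform import RigidParams, apply_transform, compose_rigid
from .volume_io import LabelMap, SeriesVolume, Volume

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "DEFAULT_EFFECT_SIZES",
    "DEFAULT_SCORE_CORRELATIONS",
    "make_phantom",
    "make_pair",
    "make_roi_labels",
    "simulate_bold",
    "simulate_cohort",
]

PHANTOM_KINDS = ("asym_blob", "cube", "sphere", "two_point")

#: standardized mean differences (EG - CG) per region; signs follow the
#: study pattern (five occipito-temporal regions decreased in patients,
#: right posterior cerebellar lobe and right cerebellum increased)
DEFAULT_EFFECT_SIZES = {
    "LMTG": -0.8, "RMTG": -0.5, "LFG": -0.5, "RIOG": -0.5,
    "LMOG": -0.5, "RPLC": 0.6, "RC": 0.5,
}

#: target Pearson correlations between region ALFF and the cognitive
#: score within the patient group
DEFAULT_SCORE_CORRELATIONS = {
    "LMTG": -0.451, "RMTG": -0.122, "LFG": -0.244, "RIOG": -0.185,
    "LMOG": -0.261, "RPLC": 0.484, "RC": 0.275,
}


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 64)
    kind: str = "asym_blob"
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"kind must be one of {PHANTOM_KINDS}, got {self.kind!r}")
        if len(self.shape) != 3 or any(s < 4 for s in self.shape):
            raise ValueError("shape must be 3 dims of at least 4 voxels")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


# Components of the asymmetric blob: (weight, center offset in units of
# shape, sigmas in units of shape).  A heavy smooth core keeps the
# intensity moments stable against additive noise; twelve compact
# satellites at mid-radius break every symmetry (so no principal-axis
# sign flip matches), give the inertia eigenvalues pairwise relative
# gaps well above 5%, and supply the high-frequency gradient structure
# an intensity metric needs to pin rotation down at realistic noise.
_ASYM_COMPONENTS = (
    (1.00, (0.00, 0.00, 0.00), (0.16, 0.115, 0.085)),
    (1.00, (0.18, 0.06, -0.05), (0.045, 0.04, 0.055)),
    (0.90, (-0.11, 0.16, 0.08), (0.04, 0.05, 0.045)),
    (1.10, (0.05, -0.17, 0.07), (0.04, 0.05, 0.042)),
    (0.95, (-0.16, -0.08, -0.13), (0.05, 0.04, 0.045)),
    (1.05, (0.10, 0.12, 0.15), (0.042, 0.046, 0.04)),
    (1.00, (-0.06, 0.03, -0.18), (0.04, 0.042, 0.05)),
    (0.95, (0.16, -0.10, 0.12), (0.046, 0.04, 0.04)),
    (1.05, (-0.17, 0.09, -0.06), (0.04, 0.05, 0.042)),
    (0.90, (0.03, 0.18, 0.03), (0.044, 0.042, 0.046)),
    (1.00, (0.11, -0.05, -0.16), (0.042, 0.048, 0.04)),
    (0.95, (-0.09, -0.16, 0.11), (0.048, 0.04, 0.044)),
    (1.00, (0.00, 0.09, 0.18), (0.04, 0.044, 0.048)),
)


def _gaussian_sum(shape, components) -> np.ndarray:
    n = np.asarray(shape, dtype=float)
    center = (n - 1) / 2.0
    xs = np.arange(shape[0])[:, None, None]
    ys = np.arange(shape[1])[None, :, None]
    zs = np.arange(shape[2])[None, None, :]
    out = np.zeros(shape, dtype=float)
    for w, off, sig in components:
        cx, cy, cz = center + np.asarray(off) * n
        sx, sy, sz = np.asarray(sig) * n
        out += w * np.exp(
            -0.5 * (((xs - cx) / sx) ** 2 + ((ys - cy) / sy) ** 2 + ((zs - cz) / sz) ** 2)
        )
    return out


def _radial_taper(shape, inner: float = 0.26, outer: float = 0.33) -> np.ndarray:
    """Smooth cosine-squared falloff to exactly zero at ``outer``·min(shape).

    Gives the registration phantom compact support well inside the field
    of view (like a head fully inside the scan), so moderate rigid
    motions never clip intensity mass at the volume boundary — boundary
    truncation would bias the second moments, which weight the faint
    tails by radius squared.
    """
    n = np.asarray(shape, dtype=float)
    center = (n - 1) / 2.0
    scale = float(n.min())
    r1, r2 = inner * scale, outer * scale
    xs = np.arange(shape[0])[:, None, None] - center[0]
    ys = np.arange(shape[1])[None, :, None] - center[1]
    zs = np.arange(shape[2])[None, None, :] - center[2]
    r = np.sqrt(xs**2 + ys**2 + zs**2)
    w = np.clip((r2 - r) / (r2 - r1), 0.0, 1.0)
    return np.sin(0.5 * np.pi * w) ** 2


def make_phantom(spec: PhantomSpec) -> Volume:
    """Deterministic 3-D phantom on a unit-spacing grid."""
    shape = tuple(int(s) for s in spec.shape)
    n = np.asarray(shape)
    if spec.kind == "asym_blob":
        data = _gaussian_sum(shape, _ASYM_COMPONENTS) * _radial_taper(shape)
    elif spec.kind == "cube":
        data = np.zeros(shape)
        lo, hi = n // 4, n - n // 4
        data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = 1.0
    elif spec.kind == "sphere":
        center = (n - 1) / 2.0
        radius = min(shape) / 4.0
        xs = np.arange(shape[0])[:, None, None]
        ys = np.arange(shape[1])[None, :, None]
        zs = np.arange(shape[2])[None, None, :]
        r2 = (xs - center[0]) ** 2 + (ys - center[1]) ** 2 + (zs - center[2]) ** 2
        data = (r2 <= radius**2).astype(float)
    else:  # two_point
        data = np.zeros(shape)
        data[shape[0] // 4, shape[1] // 2, shape[2] // 2] = 1.0
        data[3 * shape[0] // 4, shape[1] // 2, shape[2] // 2] = 2.0
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sigma, size=shape)
    return Volume(data, spacing=(1.0, 1.0, 1.0))


def make_pair(
    phantom: Volume,
    truth: RigidParams,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[Volume, Volume, RigidParams]:
    """Reference/floating pair under a known rigid motion.

    The floating image is the phantom moved by ``truth`` (rotation about
    the phantom centroid) plus optional Gaussian noise, so a registration
    run on the pair should report exactly ``truth``.  Noise is left
    unclipped: symmetric noise keeps the intensity moments unbiased.

    Raises if any angle reaches 45 degrees (recovery is no longer
    guaranteed) or the motion pushes more than 20% of the intensity mass
    out of the field of view (the problem becomes ill-posed).
    """
    if np.any(np.abs(truth.angles) >= np.pi / 4):
        raise ValueError("truth angles must stay within (-45, 45) degrees")
    center = compute_centroid(phantom)
    m = compose_rigid(truth, center)
    moved = apply_transform(phantom, m, interpolation="trilinear")
    if moved.data.sum() < 0.8 * phantom.data.sum():
        raise ValueError("motion pushes > 20% of intensity mass outside the field of view")
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        moved = Volume(
            moved.data + rng.normal(0.0, noise_sigma, size=moved.shape),
            moved.spacing,
            moved.origin,
        )
    return phantom.copy(), moved, truth


def make_roi_labels(
    shape=(16, 16, 16),
    regions=DEFAULT_REGIONS,
    spacing=(1.0, 1.0, 1.0),
) -> LabelMap:
    """Partition a grid into equal slabs along x, one ROI per region."""
    shape = tuple(int(s) for s in shape)
    k = len(regions)
    if shape[0] < k:
        raise ValueError(f"need at least {k} x-planes for {k} regions")
    labels = np.zeros(shape, dtype=np.int32)
    edges = np.linspace(0, shape[0], k + 1).astype(int)
    for j in range(k):
        labels[edges[j]:edges[j + 1]] = j + 1
    names = {j + 1: regions[j] for j in range(k)}
    return LabelMap(labels, names, spacing)


def simulate_bold(
    labels: LabelMap,
    amplitudes: dict,
    n_t: int = 200,
    tr: float = 2.5,
    noise_sigma: float = 0.0,
    drift_sigma: float | None = None,
    baseline: float = 100.0,
    band=(0.01, 0.08),
    seed: int = 0,
) -> SeriesVolume:
    """BOLD-like 4-D series with region-specific low-band sinusoids.

    ``amplitudes`` maps region name (or integer label) to the sinusoid
    amplitude of that ROI.  Each ROI is assigned its own frequency,
    evenly spread across ``band`` and snapped to the nearest exact FFT
    bin of the (n_t, tr) grid, so an ALFF analysis recovers amplitude
    ratios exactly.  White noise (sd ``noise_sigma``) and a per-voxel
    random linear drift (slope sd ``drift_sigma``; default scales the
    noise level by the scan duration) are added on top of a constant
    baseline.  Deterministic per seed.
    """
    if n_t < 2 or tr <= 0:
        raise ValueError("need n_t >= 2 and tr > 0")
    rng = np.random.default_rng(seed)
    shape = labels.labels.shape
    low, high = band
    duration = n_t * tr
    if drift_sigma is None:
        drift_sigma = noise_sigma / duration

    name_to_label = {v: k for k, v in labels.names.items()}
    amp_by_label: dict[int, float] = {}
    for key, a in amplitudes.items():
        lab = name_to_label.get(key, key)
        if not isinstance(lab, (int, np.integer)) or int(lab) not in labels.names:
            raise ValueError(f"unknown region {key!r}")
        amp_by_label[int(lab)] = float(a)

    freqs = np.fft.rfftfreq(n_t, d=tr)
    inband_bins = np.where((freqs >= low) & (freqs <= high))[0]
    if inband_bins.size < len(labels.rois):
        raise ValueError("band holds fewer frequency bins than there are regions")
    t = np.arange(n_t) * tr
    data = np.full(shape + (n_t,), float(baseline))

    rois = labels.rois
    used = set()
    for j, lab in enumerate(rois):
        target = low + (high - low) * (j + 1) / (len(rois) + 1)
        order = np.argsort(np.abs(freqs[inband_bins] - target))
        bin_idx = next(int(inband_bins[i]) for i in order if int(inband_bins[i]) not in used)
        used.add(bin_idx)
        f = freqs[bin_idx]
        if not (low <= f <= high):
            raise ValueError(f"region frequency {f} Hz outside band {band}")
        amp = amp_by_label.get(lab, 0.0)
        phase = rng.uniform(0, 2 * np.pi)
        data[labels.labels == lab] += amp * np.sin(2 * np.pi * f * t + phase)

    if noise_sigma > 0:
        data += rng.normal(0.0, noise_sigma, size=data.shape)
    if drift_sigma > 0:
        slopes = rng.normal(0.0, drift_sigma, size=shape)
        data += slopes[..., None] * t
    return SeriesVolume(data, labels.spacing, tr, labels.origin)


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort with region effects and score correlations.

    Defaults reflect the study conditions this package emulates: 107
    patients (EG) vs 51 controls (CG); MoCA-like scores 21.56 ± 4.11 vs
    29.47 ± 5.08 (truncated to the 0-30 scale after generation); the
    region effect-size signs and score correlations listed in the module
    constants.  Effect sizes are standardized mean differences in units
    of ``region_sd``.
    """

    n_eg: int = 107
    n_cg: int = 51
    regions: tuple = DEFAULT_REGIONS
    effect_sizes: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    score_eg: tuple[float, float] = (21.56, 4.11)
    score_cg: tuple[float, float] = (29.47, 5.08)
    correlations_eg: dict = field(default_factory=lambda: dict(DEFAULT_SCORE_CORRELATIONS))
    correlations_cg: dict = field(default_factory=dict)
    base_mean: float = 1.0
    region_sd: float = 0.15
    score_range: tuple[float, float] = (0.0, 30.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_eg < 2 or self.n_cg < 2:
            raise ValueError("each group needs at least 2 subjects")
        for d in (self.correlations_eg, self.correlations_cg):
            for region, rho in d.items():
                if not abs(rho) < 1:
                    raise ValueError(f"|rho| must be < 1, got {rho} for {region}")


def _copula_cholesky(regions, correlations) -> np.ndarray:
    """Cholesky factor of the (score, regions...) correlation matrix."""
    k = len(regions)
    c = np.eye(k + 1)
    for j, region in enumerate(regions):
        rho = float(correlations.get(region, 0.0))
        c[0, j + 1] = c[j + 1, 0] = rho
    try:
        return np.linalg.cholesky(c)
    except np.linalg.LinAlgError:
        worst = max(regions, key=lambda r: abs(correlations.get(r, 0.0)))
        raise ValueError(
            f"correlation targets are jointly infeasible (matrix not positive "
            f"definite); largest offender is the (score, {worst}) pair"
        ) from None


def simulate_cohort(spec: CohortSpec) -> list[CohortRecord]:
    """Draw a two-group cohort with the specified effects and correlations.

    Region ALFF values are Gaussian with the standardized group mean
    differences of ``spec.effect_sizes``; the score is drawn jointly with
    the regions through a Gaussian copula hitting ``correlations_*``
    (specified pre-truncation), then truncated to ``score_range``.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[CohortRecord] = []
    lo, hi = spec.score_range
    for group, n, (mu_s, sd_s), correlations in (
        ("EG", spec.n_eg, spec.score_eg, spec.correlations_eg),
        ("CG", spec.n_cg, spec.score_cg, spec.correlations_cg),
    ):
        chol = _copula_cholesky(spec.regions, correlations)
        z = chol @ rng.standard_normal((len(spec.regions) + 1, n))
        scores = np.clip(mu_s + sd_s * z[0], lo, hi)
        for i in range(n):
            regions = {}
            for j, region in enumerate(spec.regions):
                d = float(spec.effect_sizes.get(region, 0.0))
                mu = spec.base_mean + (d * spec.region_sd if group == "EG" else 0.0)
                regions[region] = float(mu + spec.region_sd * z[j + 1, i])
            records.append(
                CohortRecord(
                    subject_id=f"{group}{i + 1:03d}",
                    group=group,
                    score=float(scores[i]),
                    regions=regions,
                )
            )
    return records
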