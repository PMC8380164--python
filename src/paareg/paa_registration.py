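"""Principal-axis rigid registration.

The principal-axis algorithm (PAA) estimates the rigid motion between two
volumes in closed form from intensity moments: the zeroth/first moments
give each image's centroid (Cartesian intensity-weighted mean), and the
second central moments assembled into the inertia matrix

    H = [[Syy+Szz, -Sxy,    -Sxz   ],
         [-Sxy,     Sxx+Szz, -Syz  ],
         [-Sxz,    -Syz,     Sxx+Syy]]     (standardized by total mass)

give the principal axes as its eigenvectors.  Aligning the two images'
centroids and axes yields a six-parameter rigid estimate in a single
step, with no risk of local convergence — which is why it also serves as
the initializer for an iterative intensity-metric refinement.

Eigenvectors are defined only up to sign, leaving four sign-consistent
proper rotations compatible with the axes; all four candidates are
applied and the one with the best normalized cross-correlation against
the reference is kept.  Near-degenerate eigenvalue pairs (spheres, cubes)
make the axes meaningless, so such volumes fall back to centroid-only
translation with the degeneracy flagged.

Euler angles are extracted from a rotation block R = Mx(a)·My(b)·Mz(g)
(this package's composition order) via

    b = arcsin R[0,2],  a = atan2(R[1,2], R[2,2]),  g = atan2(R[0,1], R[0,0])

with the gimbal-locked case (|cos b| ~ 0) resolved by convention g := 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .rigid_transform import (
    RigidParams,
    apply_transform,
    compose_rigid,
    invert,
)
from .similarity_metrics import get_metric, metric_sign, ncc
from .volume_io import Volume

__all__ = [
    "PrincipalAxes",
    "EulerAngles",
    "RegistrationResult",
    "compute_centroid",
    "compute_inertia",
    "principal_axes",
    "extract_euler",
    "matrix_to_params",
    "register_paa",
    "refine",
    "brute_force_register",
    "align",
]

#: relative eigenvalue gap below which axes are considered degenerate
DEGENERACY_TOL = 1e-3

#: the four sign-consistent diagonal matrices with det +1
_SIGN_CANDIDATES = [
    np.diag(d)
    for d in ((1.0, 1.0, 1.0), (1.0, -1.0, -1.0), (-1.0, 1.0, -1.0), (-1.0, -1.0, 1.0))
]


@dataclass(frozen=True)
class EulerAngles:
    """Rotation angles about x, y, z in radians, plus a gimbal-lock flag."""

    alpha: float
    beta: float
    gamma: float
    gimbal_lock: bool = False

    def __iter__(self):
        return iter((self.alpha, self.beta, self.gamma))


@dataclass
class PrincipalAxes:
    """Centroid, inertia matrix and eigen-structure of one volume.

    ``eigenvalues`` are sorted descending; ``axes`` columns are the
    matching orthonormal eigenvectors with det +1 after sign fixing.
    """

    centroid: np.ndarray
    inertia: np.ndarray
    eigenvalues: np.ndarray
    axes: np.ndarray
    degenerate: bool = False
    rel_gap: float = np.inf


@dataclass
class RegistrationResult:
    """Estimated rigid motion carrying the reference onto the floating image.

    ``matrix`` is the forward motion (apply it to the reference to
    reproduce the floating image); resampling the floating image through
    its inverse (see :func:`align`) brings it into the reference frame.
    ``similarity_before/after`` compare the floating image to the
    reference before and after that alignment.
    """

    params: RigidParams
    matrix: np.ndarray
    similarity_before: float
    similarity_after: float
    iterations: int
    method: str
    metric_name: str = "ncc"
    details: dict = field(default_factory=dict)


def _grids(v: Volume):
    xs = v.origin[0] + np.arange(v.shape[0]) * v.spacing[0]
    ys = v.origin[1] + np.arange(v.shape[1]) * v.spacing[1]
    zs = v.origin[2] + np.arange(v.shape[2]) * v.spacing[2]
    return xs, ys, zs


def compute_centroid(v: Volume) -> np.ndarray:
    """Intensity-weighted mean world coordinate (mm) of a volume."""
    w = v.data
    total = w.sum()
    if total <= 0:
        raise ValueError("centroid undefined: volume has no positive mass")
    xs, ys, zs = _grids(v)
    xc = (w.sum(axis=(1, 2)) * xs).sum() / total
    yc = (w.sum(axis=(0, 2)) * ys).sum() / total
    zc = (w.sum(axis=(0, 1)) * zs).sum() / total
    return np.array([xc, yc, zc])


def compute_inertia(v: Volume, centroid=None) -> np.ndarray:
    """Standardized inertia matrix of the intensity distribution.

    Second central moments about the centroid, in world mm², normalized
    by total intensity so the result is invariant to grey-level scaling.
    """
    w = v.data
    total = w.sum()
    if total <= 0:
        raise ValueError("inertia undefined: volume has no positive mass")
    if centroid is None:
        centroid = compute_centroid(v)
    xs, ys, zs = _grids(v)
    dx, dy, dz = xs - centroid[0], ys - centroid[1], zs - centroid[2]
    sxx = np.einsum("ijk,i->", w, dx**2) / total
    syy = np.einsum("ijk,j->", w, dy**2) / total
    szz = np.einsum("ijk,k->", w, dz**2) / total
    sxy = np.einsum("ijk,i,j->", w, dx, dy) / total
    sxz = np.einsum("ijk,i,k->", w, dx, dz) / total
    syz = np.einsum("ijk,j,k->", w, dy, dz) / total
    return np.array(
        [
            [syy + szz, -sxy, -sxz],
            [-sxy, sxx + szz, -syz],
            [-sxz, -syz, sxx + syy],
        ]
    )


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector signs: dominant component positive, det +1."""
    e = vecs.copy()
    for j in range(3):
        i = int(np.argmax(np.abs(e[:, j])))
        if e[i, j] < 0:
            e[:, j] = -e[:, j]
    if np.linalg.det(e) < 0:
        e[:, 2] = -e[:, 2]
    return e


def principal_axes(v: Volume, degeneracy_tol: float = DEGENERACY_TOL) -> PrincipalAxes:
    """Eigen-decomposition of a volume's inertia matrix.

    Near-degenerate eigenvalue pairs (relative gap < ``degeneracy_tol``)
    set the ``degenerate`` flag; the axes are still returned but are not
    trustworthy for registration.
    """
    centroid = compute_centroid(v)
    h = compute_inertia(v, centroid)
    evals, evecs = np.linalg.eigh(h)  # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = _fix_signs(evecs[:, order])
    scale = max(abs(evals[0]), np.finfo(float).tiny)
    rel_gap = float(min(evals[0] - evals[1], evals[1] - evals[2]) / scale)
    return PrincipalAxes(
        centroid=centroid,
        inertia=h,
        eigenvalues=evals,
        axes=evecs,
        degenerate=rel_gap < degeneracy_tol,
        rel_gap=rel_gap,
    )


def extract_euler(r: np.ndarray, lock_tol: float = 1e-8) -> EulerAngles:
    """Recover (alpha, beta, gamma) from R = Mx(a) @ My(b) @ Mz(g).

    At gimbal lock (|cos beta| < ``lock_tol``) only alpha±gamma is
    identifiable; the convention gamma := 0 is returned with the flag set,
    and the reconstruction still reproduces R.
    """
    r = np.asarray(r, dtype=float)
    if r.shape == (4, 4):
        r = r[:3, :3]
    if r.shape != (3, 3):
        raise ValueError("expected a 3x3 rotation (or 4x4 homogeneous) matrix")
    if not np.allclose(r.T @ r, np.eye(3), atol=1e-6) or np.linalg.det(r) < 0:
        raise ValueError("matrix is not a proper rotation")
    sb = float(np.clip(r[0, 2], -1.0, 1.0))
    cb = float(np.sqrt(max(0.0, 1.0 - sb * sb)))
    if cb < lock_tol:
        beta = np.pi / 2 if sb > 0 else -np.pi / 2
        alpha = float(np.arctan2(-r[1, 0] * sb, r[1, 1]))
        return EulerAngles(alpha, beta, 0.0, gimbal_lock=True)
    beta = float(np.arcsin(sb))
    alpha = float(np.arctan2(r[1, 2], r[2, 2]))
    gamma = float(np.arctan2(r[0, 1], r[0, 0]))
    return EulerAngles(alpha, beta, gamma)


def matrix_to_params(m: np.ndarray, center=(0.0, 0.0, 0.0)) -> RigidParams:
    """Six parameters of a rigid matrix, relative to a rotation center."""
    m = np.asarray(m, dtype=float)
    e = extract_euler(m[:3, :3])
    c = np.asarray(center, dtype=float)
    l = m[:3, 3] - c + m[:3, :3] @ c
    return RigidParams(l[0], l[1], l[2], e.alpha, e.beta, e.gamma)


def _safe_ncc(a, b) -> float:
    """Masked NCC, or NaN where it is undefined (e.g. binary images whose
    overlap is constant)."""
    try:
        return ncc(a, b).value
    except ValueError:
        return float("nan")


def _motion_matrix(rot: np.ndarray, c_ref: np.ndarray, c_flt: np.ndarray) -> np.ndarray:
    """Forward motion: rotate about the reference centroid, then carry it
    onto the floating centroid."""
    m = np.eye(4)
    m[:3, :3] = rot
    m[:3, 3] = c_flt - rot @ c_ref
    return m


def align(floating: Volume, result_or_matrix, interpolation: str = "trilinear") -> Volume:
    """Resample the floating image into the reference frame of a result."""
    m = result_or_matrix.matrix if isinstance(result_or_matrix, RegistrationResult) else result_or_matrix
    return apply_transform(floating, invert(m), interpolation=interpolation)


def register_paa(
    reference: Volume,
    floating: Volume,
    degeneracy_tol: float = DEGENERACY_TOL,
) -> RegistrationResult:
    """Closed-form principal-axis registration of two volumes.

    The estimated rotation is the product of the two images' eigenvector
    matrices (relative rotation), disambiguated over the four
    sign-consistent candidates by NCC; the translation carries the
    reference centroid onto the floating centroid.  If either image's
    axes are degenerate the estimate falls back to centroid-only
    translation (method tag ``"centroid"``).
    """
    pa_ref = principal_axes(reference, degeneracy_tol)
    pa_flt = principal_axes(floating, degeneracy_tol)
    sim_before = _safe_ncc(reference, floating)
    details = {
        "centroid_ref": pa_ref.centroid,
        "centroid_flt": pa_flt.centroid,
        "eigenvalues_ref": pa_ref.eigenvalues,
        "eigenvalues_flt": pa_flt.eigenvalues,
        "degenerate_ref": pa_ref.degenerate,
        "degenerate_flt": pa_flt.degenerate,
    }

    if pa_ref.degenerate or pa_flt.degenerate:
        m = _motion_matrix(np.eye(3), pa_ref.centroid, pa_flt.centroid)
        sim_after = _safe_ncc(reference, align(floating, m))
        return RegistrationResult(
            params=matrix_to_params(m, center=pa_ref.centroid),
            matrix=m,
            similarity_before=sim_before,
            similarity_after=sim_after,
            iterations=1,
            method="centroid",
            details=details,
        )

    best = None
    for idx, d in enumerate(_SIGN_CANDIDATES):
        rot = pa_flt.axes @ d @ pa_ref.axes.T
        m = _motion_matrix(rot, pa_ref.centroid, pa_flt.centroid)
        score = _safe_ncc(reference, align(floating, m))
        better = best is None or (
            np.isfinite(score) and (not np.isfinite(best[0]) or score > best[0])
        )
        if better:
            best = (score, m, idx)
    sim_after, matrix, cand = best
    details["sign_candidate"] = cand
    return RegistrationResult(
        params=matrix_to_params(matrix, center=pa_ref.centroid),
        matrix=matrix,
        similarity_before=sim_before,
        similarity_after=sim_after,
        iterations=1,
        method="paa",
        details=details,
    )


class _ForwardObjective:
    """Intensity objective for iterative search over rigid parameters.

    Compares the *untouched* floating image against the reference
    forward-transformed by the candidate motion.  Keeping the floating
    image fixed matters: re-resampling it at every candidate pose lets
    pose-dependent interpolation blur (and noise smoothing) tilt the
    metric surface by of order a degree, whereas transforming only the
    reference leaves the noise field constant and matches the
    interpolation blur at the true pose.

    To keep each evaluation cheap without reintroducing trilinear blur,
    the reference is cubic-spline upsampled once onto a finer grid
    (factor ``upsample``) and candidate poses are evaluated by trilinear
    pulls from that model.
    """

    def __init__(self, reference: Volume, floating: Volume, center, metric: str,
                 upsample: int = 2):
        if reference.spacing != floating.spacing or reference.origin != floating.origin:
            raise ValueError("reference and floating must share one grid geometry")
        self.metric = metric
        self.metric_fn = get_metric(metric)
        self.sign = metric_sign(metric)
        self.center = np.asarray(center, dtype=float)
        self.spacing = np.asarray(reference.spacing)
        self.up = int(upsample)
        # evaluate only inside the reference support bounding box: far
        # background carries no alignment information.  The pad must be
        # generous — if the moved object crossed the window edge during the
        # search, the window would modulate the metric's normalization and
        # tilt the optimum.
        support = reference.data > 1e-4 * reference.data.max()
        pad = 8
        lo, hi = [], []
        for ax in range(3):
            proj = support.any(axis=tuple(i for i in range(3) if i != ax))
            idx = np.where(proj)[0]
            lo.append(max(0, idx[0] - pad))
            hi.append(min(reference.shape[ax], idx[-1] + pad + 1))
        self.box = tuple(slice(l, h) for l, h in zip(lo, hi))
        self.shape = tuple(h - l for l, h in zip(lo, hi))
        self.origin_in = np.asarray(reference.origin)
        self.origin_out = self.origin_in + np.array(lo) * self.spacing
        self.floating32 = floating.data[self.box].astype(np.float32)
        # model[j] = reference interpolated at voxel index j / up (exact mapping)
        coeff = ndimage.spline_filter(reference.data, order=3)
        self.model = ndimage.affine_transform(
            coeff, np.diag([1.0 / self.up] * 3),
            output_shape=tuple(s * self.up for s in self.shape),
            order=3, prefilter=False, mode="constant", cval=0.0,
        ).astype(np.float32)
        self.n_eval = 0

    def _moved_reference(self, m: np.ndarray, stride: int) -> np.ndarray:
        # reference forward-moved by m: out(x) = reference(m^-1 . x),
        # sampled on every stride-th grid voxel
        minv = invert(m)
        out_shape = tuple((s + stride - 1) // stride for s in self.shape)
        s_out = np.diag(self.spacing * stride)
        s_in_inv = np.diag(1.0 / self.spacing)
        a = self.up * s_in_inv @ minv[:3, :3] @ s_out
        offset = self.up * (s_in_inv @ (minv[:3, :3] @ self.origin_out + minv[:3, 3] - self.origin_in))
        return ndimage.affine_transform(
            self.model, a, offset=offset, output_shape=out_shape,
            order=1, prefilter=False, mode="constant", cval=0.0,
        )

    def __call__(self, q, stride: int = 1) -> float:
        self.n_eval += 1
        m = compose_rigid(RigidParams.from_array(q), self.center)
        moved = self._moved_reference(m, stride)
        target = self.floating32[::stride, ::stride, ::stride]
        if self.metric == "ncc":
            val = _fast_ncc(target, moved)
        else:
            try:
                val = self.metric_fn(target, moved).value
            except ValueError:
                return np.inf
        if not np.isfinite(val):
            return np.inf
        return -self.sign * float(val)


def _fast_ncc(x: np.ndarray, y: np.ndarray) -> float:
    """Unmasked Pearson correlation via accumulated sums (hot path)."""
    x = x.ravel()
    y = y.ravel()
    n = x.size
    sx = x.sum(dtype=np.float64)
    sy = y.sum(dtype=np.float64)
    cov = float(np.dot(x, y)) - sx * sy / n
    vx = float(np.dot(x, x)) - sx * sx / n
    vy = float(np.dot(y, y)) - sy * sy / n
    if vx <= 0 or vy <= 0:
        return np.nan
    return cov / np.sqrt(vx * vy)


_DEG = np.pi / 180.0


def refine(
    reference: Volume,
    floating: Volume,
    init: RigidParams,
    metric: str = "ncc",
    center=None,
    max_evals: int = 500,
    subsample: int = 2,
) -> RegistrationResult:
    """Derivative-free refinement of the six parameters (Powell search).

    Starts from ``init`` (typically the PAA estimate) and locally
    optimizes the chosen intensity metric in two Powell passes with
    parameter-scaled steps (1 mm / 1 degree, then 0.3 of that): a cheap
    pass on a ``subsample``-strided grid followed by a full-resolution
    polish.  The search never returns a worse objective value than the
    initialization; ``iterations`` counts objective evaluations.
    """
    if center is None:
        center = compute_centroid(reference)
    obj = _ForwardObjective(reference, floating, center, metric)
    x0 = init.as_array()
    f0 = obj(x0)
    direc = np.diag([1.0, 1.0, 1.0, _DEG, _DEG, _DEG])
    budget1 = max(1, int(max_evals * 0.6))
    budget2 = max(1, max_evals - budget1)
    failed = False
    try:
        r1 = optimize.minimize(
            lambda q: obj(q, stride=subsample), x0, method="Powell",
            options={"maxfev": budget1, "xtol": 1e-3, "ftol": 1e-7, "direc": direc},
        )
        r2 = optimize.minimize(
            obj, r1.x, method="Powell",
            options={"maxfev": budget2, "xtol": 1e-4, "ftol": 1e-9, "direc": direc * 0.3},
        )
        x_best, f_best = r2.x, float(r2.fun)
    except Exception:
        x_best, f_best, failed = x0, f0, True
    if not np.isfinite(f_best) or f_best > f0:
        x_best, f_best = x0, f0  # never degrade the init

    params = RigidParams.from_array(x_best)
    matrix = compose_rigid(params, np.asarray(center, dtype=float))
    metric_fn = get_metric(metric)
    sim_before = metric_fn(reference, floating).value
    sim_after = metric_fn(reference, align(floating, matrix)).value
    return RegistrationResult(
        params=params,
        matrix=matrix,
        similarity_before=sim_before,
        similarity_after=sim_after,
        iterations=max(obj.n_eval, 1),
        method="paa+refine",
        metric_name=metric,
        details={"center": np.asarray(center, dtype=float), "optimizer_failed": failed,
                 "objective_init": f0, "objective_final": f_best},
    )


def brute_force_register(
    reference: Volume,
    floating: Volume,
    grid: dict[str, np.ndarray],
    center=None,
    subsample: int = 1,
) -> RegistrationResult:
    """Exhaustive NCC-maximizing grid search (validation oracle).

    ``grid`` maps parameter names (l1, l2, l3, m4, m5, m6) to candidate
    value arrays; omitted parameters are fixed at zero.  Uses the same
    forward objective as :func:`refine` so results are directly
    comparable.  Deterministic given the grid.
    """
    names = ("l1", "l2", "l3", "m4", "m5", "m6")
    unknown = set(grid) - set(names)
    if unknown:
        raise ValueError(f"unknown grid parameters: {sorted(unknown)}")
    axes = [np.atleast_1d(np.asarray(grid.get(n, [0.0]), dtype=float)) for n in names]
    if any(a.size == 0 for a in axes):
        raise ValueError("empty parameter grid")
    if center is None:
        center = compute_centroid(reference)
    obj = _ForwardObjective(reference, floating, center, "ncc")

    best_q, best_f = None, np.inf
    for combo in itertools.product(*axes):
        f = obj(np.asarray(combo), stride=subsample)
        if f < best_f:
            best_f, best_q = f, combo
    if best_q is None or not np.isfinite(best_f):
        raise ValueError("no grid point produced a defined similarity")
    params = RigidParams(*best_q)
    matrix = compose_rigid(params, np.asarray(center, dtype=float))
    return RegistrationResult(
        params=params,
        matrix=matrix,
        similarity_before=ncc(reference, floating).value,
        similarity_after=ncc(reference, align(floating, matrix)).value,
        iterations=obj.n_eval,
        method="brute_force",
        details={"center": np.asarray(center, dtype=float), "objective_best": best_f},
    )
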