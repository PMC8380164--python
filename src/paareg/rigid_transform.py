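"""Six-parameter rigid transforms in homogeneous coordinates.

A rigid motion of the head is parameterized by the vector
``q = (l1, l2, l3, m4, m5, m6)``: translations along x, y, z in mm and
rotation angles about x, y, z in radians.  The overall rotation is the
ordered product ``M = Mx(m4) @ My(m5) @ Mz(m6)``; the composite matrix
rotates about an explicit world-space center (by default a volume
centroid, since rotating the head about the grid corner is never what
registration wants) and then translates:

    T = T(center) @ T(l) @ M @ T(-center)

Element signs of the single-axis matrices follow the row convention with
``+sin`` above the diagonal for the x and z axes — the transpose of the
textbook active rotation — and ``My = [[c,0,s],[0,1,0],[-s,0,c]]``.  All
matrices are orthonormal with determinant +1, so only angle sign
conventions differ from other packages.

``apply_transform`` resamples with pull semantics: each output voxel is
looked up through the inverse map, and voxels mapped outside the field of
view are zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume_io import Volume

__all__ = [
    "RigidParams",
    "translation_matrix",
    "rotation_matrix",
    "compose_rigid",
    "rotation_block",
    "is_rigid",
    "invert",
    "apply_transform",
    "save_transform",
    "load_transform",
]

_RIGID_TOL = 1e-9


def _canonical_angle(a: float) -> float:
    """Wrap an angle to (-pi, pi]."""
    a = float(a)
    a = (a + np.pi) % (2.0 * np.pi) - np.pi
    if a == -np.pi:
        a = np.pi
    return a


@dataclass(frozen=True)
class RigidParams:
    """The six-parameter rigid vector: mm translations, radian rotations."""

    l1: float = 0.0
    l2: float = 0.0
    l3: float = 0.0
    m4: float = 0.0
    m5: float = 0.0
    m6: float = 0.0

    def __post_init__(self) -> None:
        vals = [self.l1, self.l2, self.l3, self.m4, self.m5, self.m6]
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"rigid parameters must be finite, got {vals}")
        for name in ("m4", "m5", "m6"):
            object.__setattr__(self, name, _canonical_angle(getattr(self, name)))
        for name in ("l1", "l2", "l3"):
            object.__setattr__(self, name, float(getattr(self, name)))

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.l1, self.l2, self.l3])

    @property
    def angles(self) -> np.ndarray:
        return np.array([self.m4, self.m5, self.m6])

    def as_array(self) -> np.ndarray:
        return np.array([self.l1, self.l2, self.l3, self.m4, self.m5, self.m6])

    @classmethod
    def from_array(cls, q) -> "RigidParams":
        q = np.asarray(q, dtype=float)
        if q.shape != (6,):
            raise ValueError(f"expected 6 parameters, got shape {q.shape}")
        return cls(*q)


def translation_matrix(l1: float, l2: float, l3: float) -> np.ndarray:
    """Homogeneous matrix translating points by (l1, l2, l3) mm."""
    if not np.all(np.isfinite([l1, l2, l3])):
        raise ValueError("translation components must be finite")
    t = np.eye(4)
    t[:3, 3] = (l1, l2, l3)
    return t


def rotation_matrix(axis: str, angle: float) -> np.ndarray:
    """Homogeneous single-axis rotation matrix (see module conventions)."""
    if not np.isfinite(angle):
        raise ValueError("rotation angle must be finite")
    c, s = np.cos(angle), np.sin(angle)
    m = np.eye(4)
    if axis == "x":
        m[1:3, 1:3] = [[c, s], [-s, c]]
    elif axis == "y":
        m[0, 0], m[0, 2], m[2, 0], m[2, 2] = c, s, -s, c
    elif axis == "z":
        m[0:2, 0:2] = [[c, s], [-s, c]]
    else:
        raise ValueError(f"axis must be one of 'x', 'y', 'z', got {axis!r}")
    return m


def compose_rigid(p: RigidParams, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Full rigid matrix T(center) @ T(l) @ Mx @ My @ Mz @ T(-center).

    ``center`` is the world point (mm) the rotation pivots about.
    """
    if not isinstance(p, RigidParams):
        p = RigidParams.from_array(np.asarray(p, dtype=float))
    cx, cy, cz = (float(c) for c in center)
    m = (
        translation_matrix(cx, cy, cz)
        @ translation_matrix(p.l1, p.l2, p.l3)
        @ rotation_matrix("x", p.m4)
        @ rotation_matrix("y", p.m5)
        @ rotation_matrix("z", p.m6)
        @ translation_matrix(-cx, -cy, -cz)
    )
    m[3, :] = (0.0, 0.0, 0.0, 1.0)
    return m


def rotation_block(m: np.ndarray) -> np.ndarray:
    return np.asarray(m, dtype=float)[:3, :3]


def is_rigid(m: np.ndarray, tol: float = 1e-9) -> bool:
    """True when the upper 3x3 block is orthonormal with det +1."""
    m = np.asarray(m, dtype=float)
    if m.shape != (4, 4) or not np.allclose(m[3], [0, 0, 0, 1], atol=tol):
        return False
    r = m[:3, :3]
    return bool(
        np.allclose(r.T @ r, np.eye(3), atol=max(tol, 1e-12))
        and abs(np.linalg.det(r) - 1.0) <= max(tol, 1e-12)
    )


def invert(m: np.ndarray) -> np.ndarray:
    """Inverse of a homogeneous matrix; closed form (R^T) when rigid."""
    m = np.asarray(m, dtype=float)
    if m.shape != (4, 4):
        raise ValueError("expected a 4x4 homogeneous matrix")
    if is_rigid(m, tol=1e-8):
        r = m[:3, :3]
        out = np.eye(4)
        out[:3, :3] = r.T
        out[:3, 3] = -r.T @ m[:3, 3]
        return out
    det = np.linalg.det(m)
    if abs(det) < 1e-15:
        raise np.linalg.LinAlgError("singular transform matrix")
    return np.linalg.inv(m)


_INTERP_ORDER = {"nearest": 0, "trilinear": 1}


def apply_transform(
    v: Volume,
    m: np.ndarray,
    interpolation: str = "trilinear",
    strict: bool = False,
) -> Volume:
    """Resample ``v`` under the forward spatial map ``m`` (pull semantics).

    The output volume keeps the input grid, spacing and origin; output
    voxel world coordinates are pulled through ``m``:sup:`-1` and
    interpolated in the input.  Out-of-field voxels are zero.

    With ``strict=True`` a non-rigid matrix raises; otherwise it is
    accepted with a warning (useful for plumbing general affines).
    """
    if interpolation not in _INTERP_ORDER:
        raise ValueError(f"interpolation must be one of {sorted(_INTERP_ORDER)}")
    m = np.asarray(m, dtype=float)
    if not is_rigid(m, tol=1e-6):
        if strict:
            raise ValueError("matrix is not rigid (orthonormality violated)")
        warnings.warn("applying a non-rigid matrix; proceeding (affine plumbing)", stacklevel=2)
    m_inv = invert(m)
    # Index-space pull map: out index -> world -> inverse map -> input index.
    s = np.diag(v.spacing)
    s_inv = np.diag([1.0 / sp for sp in v.spacing])
    o = np.asarray(v.origin)
    a = s_inv @ m_inv[:3, :3] @ s
    offset = s_inv @ (m_inv[:3, :3] @ o + m_inv[:3, 3] - o)
    out = ndimage.affine_transform(
        v.data,
        a,
        offset=offset,
        order=_INTERP_ORDER[interpolation],
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    return Volume(out, v.spacing, v.origin)


def save_transform(path, m: np.ndarray, params: RigidParams | None = None, center=None) -> None:
    """Write a 4x4 matrix as row-major text plus a JSON parameter sidecar."""
    path = Path(path)
    np.savetxt(path, np.asarray(m, dtype=float), fmt="%.17g")
    sidecar = {"matrix_file": path.name}
    if params is not None:
        sidecar["params"] = {
            "l1": params.l1, "l2": params.l2, "l3": params.l3,
            "m4": params.m4, "m5": params.m5, "m6": params.m6,
        }
    if center is not None:
        sidecar["center"] = [float(c) for c in center]
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_transform(path):
    """Read a transform written by :func:`save_transform`.

    Returns ``(matrix, params_or_None, center_or_None)``.
    """
    path = Path(path)
    m = np.loadtxt(path)
    if m.shape != (4, 4):
        raise ValueError(f"{path}: expected a 4x4 matrix, got {m.shape}")
    params = center = None
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        doc = json.loads(sidecar.read_text())
        if "params" in doc:
            params = RigidParams(**doc["params"])
        if "center" in doc:
            center = tuple(doc["center"])
    return m, params, center
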