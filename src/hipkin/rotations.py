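"""Quaternion and rotation-matrix algebra.

Conventions
-----------
Quaternions are scalar-first unit 4-vectors ``q = (q0, qx, qy, qz)`` in the
Hamilton convention.  A quaternion ``q21`` describing the orientation of
frame 2 relative to frame 1 rotates frame-2 coordinates into frame-1
coordinates::

    v1 = q21 (x) [0, v2] (x) q21^-1  <=>  v1 = R(q21) v2

The sign ambiguity (``q`` and ``-q`` encode the same rotation) is resolved
by :func:`quat_canonical`: scalar part non-negative, and when the scalar
part is (numerically) zero the first nonzero vector component is positive.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DegenerateAxisError, InvalidInputError, InvalidRotationError

__all__ = [
    "quat_identity",
    "quat_normalize",
    "quat_canonical",
    "quat_conjugate",
    "quat_multiply",
    "quat_rotate",
    "quat_to_matrix",
    "matrix_to_quat",
    "quat_from_axis_angle",
    "quat_from_two_vectors",
    "quat_operator_matrix",
    "axis_angle_magnitude",
    "skew",
]

_UNIT_TOL = 1e-9


def _as_finite(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return a


def quat_identity() -> np.ndarray:
    return np.array([1.0, 0.0, 0.0, 0.0])


def quat_normalize(q) -> np.ndarray:
    q = _as_finite(q, "quaternion")
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n == 0.0):
        raise InvalidInputError("zero-norm quaternion cannot be normalized")
    return q / n


def quat_canonical(q, tol: float = 1e-12) -> np.ndarray:
    """Return the canonical representative of {q, -q} (unit norm enforced)."""
    q = quat_normalize(q)
    if q.ndim == 1:
        return _canonical_one(q, tol)
    return np.array([_canonical_one(row, tol) for row in q])


def _canonical_one(q: np.ndarray, tol: float) -> np.ndarray:
    if q[0] > tol:
        return q
    if q[0] < -tol:
        return -q
    # scalar part ~ 0: make the first nonzero vector component positive
    for comp in q[1:]:
        if abs(comp) > tol:
            return q if comp > 0 else -q
    return q


def quat_conjugate(q) -> np.ndarray:
    q = _as_finite(q, "quaternion")
    out = q.copy()
    out[..., 1:] = -out[..., 1:]
    return out


def quat_multiply(q, p) -> np.ndarray:
    """Hamilton product q (x) p, renormalized to unit length."""
    q = _as_finite(q, "q")
    p = _as_finite(p, "p")
    q0, qv = q[..., 0], q[..., 1:]
    p0, pv = p[..., 0], p[..., 1:]
    s = q0 * p0 - np.sum(qv * pv, axis=-1)
    v = (q0[..., None] * pv + p0[..., None] * qv + np.cross(qv, pv))
    out = np.concatenate([s[..., None], v], axis=-1)
    return quat_normalize(out)


def quat_rotate(q, v) -> np.ndarray:
    """Rotate vector(s) ``v`` by unit quaternion(s) ``q``.

    Equivalent to ``quat_to_matrix(q) @ v`` but computed directly.
    """
    q = _as_finite(q, "q")
    v = _as_finite(v, "v")
    q0, qv = q[..., 0:1], q[..., 1:]
    t = 2.0 * np.cross(qv, v)
    return v + q0 * t + np.cross(qv, t)


def quat_to_matrix(q) -> np.ndarray:
    q = quat_normalize(q)
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    R = np.empty(q.shape[:-1] + (3, 3))
    R[..., 0, 0] = 1 - 2 * (y * y + z * z)
    R[..., 0, 1] = 2 * (x * y - w * z)
    R[..., 0, 2] = 2 * (x * z + w * y)
    R[..., 1, 0] = 2 * (x * y + w * z)
    R[..., 1, 1] = 1 - 2 * (x * x + z * z)
    R[..., 1, 2] = 2 * (y * z - w * x)
    R[..., 2, 0] = 2 * (x * z - w * y)
    R[..., 2, 1] = 2 * (y * z + w * x)
    R[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return R


def check_rotation_matrix(R, tol: float = 1e-9) -> np.ndarray:
    R = _as_finite(R, "rotation matrix")
    if R.shape[-2:] != (3, 3):
        raise InvalidRotationError(f"expected 3x3 matrix, got shape {R.shape}")
    err = np.max(np.abs(np.swapaxes(R, -1, -2) @ R - np.eye(3)))
    if err > tol:
        raise InvalidRotationError(f"matrix is not orthonormal (|R'R - I| = {err:.3g})")
    if np.any(np.abs(np.linalg.det(R) - 1.0) > max(tol, 1e-9)):
        raise InvalidRotationError("matrix determinant is not +1")
    return R


def matrix_to_quat(R) -> np.ndarray:
    """Convert a proper rotation matrix to its canonical unit quaternion."""
    R = check_rotation_matrix(R, tol=1e-6)
    # Shepperd's method: pick the largest of the four candidate pivots.
    t = np.trace(R)
    cand = np.array([t, R[0, 0], R[1, 1], R[2, 2]])
    i = int(np.argmax(cand))
    if i == 0:
        r = np.sqrt(1.0 + t)
        s = 0.5 / r
        q = np.array([0.5 * r, (R[2, 1] - R[1, 2]) * s,
                      (R[0, 2] - R[2, 0]) * s, (R[1, 0] - R[0, 1]) * s])
    else:
        j, k = (i % 3), ((i + 1) % 3)
        i -= 1
        r = np.sqrt(1.0 + R[i, i] - R[j, j] - R[k, k])
        s = 0.5 / r
        q = np.empty(4)
        q[0] = (R[k, j] - R[j, k]) * s
        q[1 + i] = 0.5 * r
        q[1 + j] = (R[j, i] + R[i, j]) * s
        q[1 + k] = (R[k, i] + R[i, k]) * s
    return quat_canonical(q)


def quat_from_axis_angle(axis, angle_rad: float) -> np.ndarray:
    axis = _as_finite(axis, "axis")
    n = np.linalg.norm(axis)
    if n == 0:
        raise DegenerateAxisError("zero rotation axis")
    axis = axis / n
    half = 0.5 * angle_rad
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def quat_from_two_vectors(u, v, parallel_tol: float = 1e-6) -> np.ndarray:
    """Quaternion rotating unit vector ``u`` onto unit vector ``v``.

    The rotation is the half-angle construction about ``u x v`` with angle
    ``arccos(u . v)``.  Near-parallel inputs (angle below ``parallel_tol``
    radians) return the identity; antiparallel inputs raise because the
    axis is undefined.
    """
    u = _as_finite(u, "u")
    v = _as_finite(v, "v")
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    d = float(np.clip(np.dot(u, v), -1.0, 1.0))
    if d < -1.0 + 1e-8:
        raise DegenerateAxisError("antiparallel vectors: rotation axis undefined")
    angle = np.arccos(d)
    if angle < parallel_tol:
        return quat_identity()
    axis = np.cross(u, v)
    axis = axis / np.linalg.norm(axis)
    return np.concatenate([[np.cos(0.5 * angle)], np.sin(0.5 * angle) * axis])


def quat_operator_matrix(q) -> np.ndarray:
    """The 4x4 quaternion operator matrix ``q(x)``.

    For a pure quaternion ``w = (0, omega)`` this operator satisfies
    ``quat_operator_matrix(w) @ p == -(p (x) w)`` so that the relative
    orientation kinematics ``qdot = -1/2 w(x) q`` expand to the body-rate
    form ``qdot = +1/2 q (x) (0, omega)``.
    """
    q = _as_finite(q, "q")
    q0, qx, qy, qz = q
    return np.array([
        [q0, qx, qy, qz],
        [-qx, q0, -qz, qy],
        [-qy, qz, q0, -qx],
        [-qz, -qy, qx, q0],
    ])


def axis_angle_magnitude(R) -> float:
    """Rotation angle of ``R`` in degrees, in [0, 180]."""
    R = _as_finite(R, "R")
    if R.ndim == 3:
        return np.array([axis_angle_magnitude(Ri) for Ri in R])
    check_rotation_matrix(R, tol=1e-6)
    c = (np.trace(R) - 1.0) / 2.0
    if c > 1.0 + 1e-9 or c < -1.0 - 1e-9:
        raise InvalidRotationError(f"trace {np.trace(R):.6f} outside valid range")
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def skew(v) -> np.ndarray:
    """Skew-symmetric cross-product matrix: ``skew(v) @ u == cross(v, u)``."""
    v = _as_finite(v, "v")
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
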