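"""Functional joint-center and hinge-axis estimation.

A ball joint shared by two sensed segments constrains the joint-center
acceleration computed from either sensor to agree up to the frames'
relative rotation::

    a1 - ([w1 x][w1 x] + [w1' x]) r1 = R21 ( a2 - ([w2 x][w2 x] + [w2' x]) r2 )

Stacking this over many high-angular-velocity samples gives an
overdetermined linear system in the constant center-to-sensor vectors
``r1`` (sensor-1 frame) and ``r2`` (sensor-2 frame), solved by least
squares.  For quasi-1-DoF joints (the knee) the component of the center
along the hinge axis is unobservable; the axis is identified from the
constraint that both sensors see the same angular-velocity magnitude
around it, and the center estimate is then shifted to the axis point
nearest the sensors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .exceptions import (
    ConvergenceError,
    DegenerateMotionError,
    InsufficientDataError,
    InvalidInputError,
)
from .preprocess import ImuRecording, angular_acceleration
from .rotations import skew

__all__ = [
    "JointCenterResult",
    "HingeAxes",
    "select_high_motion_samples",
    "estimate_joint_center",
    "estimate_hinge_axes",
    "correct_hinge_center",
]

MIN_OBSERVATIONS = 1500
CONDITION_LIMIT = 1e8


@dataclass
class JointCenterResult:
    """Joint-center-to-sensor vectors with the least-squares fit residual."""

    r1: np.ndarray        # center -> sensor-1 origin, m, sensor-1 frame
    r2: np.ndarray        # center -> sensor-2 origin, m, sensor-2 frame
    residual: float       # RMS residual of the stacked system, m/s^2
    n_obs: int
    condition: float = np.nan


@dataclass
class HingeAxes:
    """Hinge rotation axis expressed in each sensor's frame (unit vectors)."""

    j1: np.ndarray
    j2: np.ndarray
    cost: float = np.nan

    def __post_init__(self):
        self.j1 = np.asarray(self.j1, dtype=float)
        self.j2 = np.asarray(self.j2, dtype=float)
        for j in (self.j1, self.j2):
            if abs(np.linalg.norm(j) - 1.0) > 1e-9:
                raise InvalidInputError("hinge axes must be unit vectors")


def select_high_motion_samples(w1, w2, n_min: int = MIN_OBSERVATIONS) -> np.ndarray:
    """Indices of the ``n_min`` samples with the largest combined gyro norm.

    Samples are ranked by ``|w1| + |w2|`` (descending, ties broken toward
    the earlier index) and returned sorted ascending in time.
    """
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    n = w1.shape[0]
    if n < n_min:
        raise InsufficientDataError(
            f"need at least {n_min} samples for joint-center estimation, got {n}")
    score = np.linalg.norm(w1, axis=1) + np.linalg.norm(w2, axis=1)
    order = np.argsort(-score, kind="stable")
    return np.sort(order[:n_min])


def estimate_joint_center(imu1: ImuRecording, imu2: ImuRecording, R21_trace,
                          indices=None, n_min: int = MIN_OBSERVATIONS
                          ) -> JointCenterResult:
    """Least-squares joint-center vectors from the stacked ball-joint system.

    ``R21_trace`` is the per-sample rotation from sensor-2 to sensor-1
    coordinates (typically from the SSRO filter).  ``indices`` defaults to
    the high-angular-velocity selection.  A condition number above 1e8
    signals motion that does not excite all rotational degrees of freedom
    and raises :class:`DegenerateMotionError`.
    """
    R21_trace = np.asarray(R21_trace, dtype=float)
    if R21_trace.shape[0] != len(imu1) or len(imu1) != len(imu2):
        raise InvalidInputError("recordings and rotation trace must be aligned")
    if indices is None:
        indices = select_high_motion_samples(imu1.gyro, imu2.gyro, n_min=n_min)
    indices = np.asarray(indices, dtype=int)

    wd1 = angular_acceleration(imu1.gyro, imu1.dt)
    wd2 = angular_acceleration(imu2.gyro, imu2.dt)

    n = len(indices)
    A = np.empty((3 * n, 6))
    b = np.empty(3 * n)
    for row, k in enumerate(indices):
        K1 = skew(imu1.gyro[k]) @ skew(imu1.gyro[k]) + skew(wd1[k])
        K2 = skew(imu2.gyro[k]) @ skew(imu2.gyro[k]) + skew(wd2[k])
        R = R21_trace[k]
        A[3 * row:3 * row + 3, 0:3] = K1
        A[3 * row:3 * row + 3, 3:6] = -R @ K2
        b[3 * row:3 * row + 3] = imu1.accel[k] - R @ imu2.accel[k]

    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise DegenerateMotionError(
            f"design matrix condition number {cond:.3g} exceeds {CONDITION_LIMIT:.0e}: "
            "motion does not constrain the joint center in 3D")
    x, res, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    resid = A @ x - b
    return JointCenterResult(r1=x[0:3], r2=x[3:6],
                             residual=float(np.sqrt(np.mean(resid ** 2))),
                             n_obs=n, condition=float(cond))


def _axes_from_spherical(p):
    t1, p1, t2, p2 = p
    j1 = np.array([np.sin(t1) * np.cos(p1), np.sin(t1) * np.sin(p1), np.cos(t1)])
    j2 = np.array([np.sin(t2) * np.cos(p2), np.sin(t2) * np.sin(p2), np.cos(t2)])
    return j1, j2


def hinge_cost(j1, j2, w1, w2) -> float:
    """Sum of squared differences of angular-velocity magnitudes about the axes."""
    n1 = np.linalg.norm(np.cross(w1, j1), axis=1)
    n2 = np.linalg.norm(np.cross(w2, j2), axis=1)
    return float(np.sum((n1 - n2) ** 2))


def estimate_hinge_axes(w1, w2, max_iter: int = 500) -> HingeAxes:
    """Hinge axis in each sensor frame from the shared-magnitude constraint.

    Each axis is parameterized by spherical angles (unit norm guaranteed)
    and the cost is minimized with a gradient-based optimizer from eight
    deterministic diagonal starts; the best local optimum is kept.  Axis
    polarity is disambiguated so that the projections of the two angular
    velocities onto their axes are positively correlated.
    """
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if w1.shape != w2.shape or w1.ndim != 2:
        raise InvalidInputError("angular velocity arrays must share shape (N, 3)")

    def cost(p):
        j1, j2 = _axes_from_spherical(p)
        return hinge_cost(j1, j2, w1, w2)

    starts = []
    for sx in (1.0, -1.0):
        for sy in (1.0, -1.0):
            for sz in (1.0, -1.0):
                v = np.array([sx, sy, sz]) / np.sqrt(3.0)
                t = np.arccos(v[2])
                ph = np.arctan2(v[1], v[0])
                starts.append([t, ph, t, ph])

    best = None
    any_converged = False
    for p0 in starts:
        res = optimize.minimize(cost, p0, method="BFGS",
                                options={"maxiter": max_iter})
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_converged and best.fun > 1e-6 * w1.shape[0]:
        raise ConvergenceError(
            f"hinge-axis optimization did not converge (cost {best.fun:.3g})",
            final_cost=float(best.fun))

    j1, j2 = _axes_from_spherical(best.x)
    if float(np.sum((w1 @ j1) * (w2 @ j2))) < 0.0:
        j2 = -j2
    return HingeAxes(j1=j1, j2=j2, cost=float(best.fun))


def correct_hinge_center(r_hat1, r_hat2, axes: HingeAxes):
    """Shift a hinge-joint center estimate to the axis point nearest the sensors.

    ``r_i = r^_i - j_i ((r^1 . j1) + (r^2 . j2)) / 2``; afterwards the
    corrected vectors satisfy ``(r1 . j1) + (r2 . j2) = 0``.
    """
    r_hat1 = np.asarray(r_hat1, dtype=float)
    r_hat2 = np.asarray(r_hat2, dtype=float)
    shift = 0.5 * (np.dot(r_hat1, axes.j1) + np.dot(r_hat2, axes.j2))
    return r_hat1 - axes.j1 * shift, r_hat2 - axes.j2 * shift
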