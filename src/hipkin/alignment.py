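"""Sensor-to-segment anatomical calibration.

Builds the constant pelvis and thigh anatomical frames from functional
joint-center estimates and a static standing trial, following the ISB
axis conventions: the pelvis fixed axis runs from the left to the right
hip center (pelvis Z), each thigh fixed axis runs from the knee center to
the hip center (thigh y).  During the stillest window of the static trial
the thigh axes are rotated into the pelvis sensor frame, the hip joint
coordinate systems are formed (``e2 = e3 x e1``), and orthonormal
right-handed frames are assembled:

* pelvis: ``Z = e1``, ``X = normalize(mean(e2_left, e2_right))``,
  ``Y = Z x X`` (re-orthogonalized),
* thigh:  ``y = e3``, ``x = e2`` of the same side expressed back in the
  thigh sensor frame, ``z = x x y`` (re-orthogonalized).

Because every axis is derived from joint centers and relative
orientations, the construction is invariant to how the sensors are
mounted on the segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .exceptions import (
    DegenerateGeometryError,
    DegeneratePoseError,
    InsufficientDataError,
    InvalidInputError,
)
from .preprocess import ImuRecording
from .rotations import check_rotation_matrix, quat_rotate

__all__ = [
    "AnatomicalCalibration",
    "find_still_period",
    "pelvis_fixed_axis",
    "thigh_fixed_axis",
    "build_frames",
    "mean_quaternion",
    "calibrate_from_centers",
]

DEFAULT_STILL_WINDOW_S = 1.0


@dataclass
class AnatomicalCalibration:
    """Constant sensor-to-segment frames for the pelvis and both thighs.

    Each frame is a rotation matrix whose columns are the anatomical axes
    expressed in the corresponding sensor frame.
    """

    pelvis_frame: np.ndarray
    thigh_frame_left: np.ndarray
    thigh_frame_right: np.ndarray
    fixed_axes: dict = field(default_factory=dict)
    still_window: tuple | None = None

    def __post_init__(self):
        for name in ("pelvis_frame", "thigh_frame_left", "thigh_frame_right"):
            R = np.asarray(getattr(self, name), dtype=float)
            check_rotation_matrix(R)
            setattr(self, name, R)

    def thigh_frame(self, side: str) -> np.ndarray:
        if side == "left":
            return self.thigh_frame_left
        if side == "right":
            return self.thigh_frame_right
        raise InvalidInputError(f"unknown side {side!r}")

    def save(self, path) -> None:
        doc = {
            "pelvis_frame": self.pelvis_frame.tolist(),
            "thigh_frame_left": self.thigh_frame_left.tolist(),
            "thigh_frame_right": self.thigh_frame_right.tolist(),
            "fixed_axes": {k: np.asarray(v).tolist()
                           for k, v in self.fixed_axes.items()},
            "still_window": list(self.still_window) if self.still_window else None,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def load(cls, path) -> "AnatomicalCalibration":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            pelvis_frame=np.array(doc["pelvis_frame"]),
            thigh_frame_left=np.array(doc["thigh_frame_left"]),
            thigh_frame_right=np.array(doc["thigh_frame_right"]),
            fixed_axes={k: np.array(v) for k, v in (doc.get("fixed_axes") or {}).items()},
            still_window=tuple(doc["still_window"]) if doc.get("still_window") else None,
        )


def find_still_period(imu: ImuRecording,
                      window: float = DEFAULT_STILL_WINDOW_S) -> tuple:
    """Most-still window of a static trial as a ``(start, stop)`` index range.

    Stillness is the summed sliding variance of the gyro-norm and
    accel-norm series; ties break toward the earliest window.
    """
    w = int(round(window * imu.fs))
    if w < 2:
        w = 2
    n = len(imu)
    if n < w:
        raise InsufficientDataError(
            f"recording ({n} samples) shorter than still window ({w} samples)")
    score = np.zeros(n - w + 1)
    for series in (np.linalg.norm(imu.gyro, axis=1),
                   np.linalg.norm(imu.accel, axis=1)):
        c1 = np.concatenate([[0.0], np.cumsum(series)])
        c2 = np.concatenate([[0.0], np.cumsum(series ** 2)])
        s1 = c1[w:] - c1[:-w]
        s2 = c2[w:] - c2[:-w]
        var = np.maximum(s2 / w - (s1 / w) ** 2, 0.0)
        score += var
    # earliest window among numerical ties
    tol = 1e-12 * max(1.0, float(score.max()))
    start = int(np.flatnonzero(score <= score.min() + tol)[0])
    return (start, start + w)


def _unit_between(a, b, what: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = a - b
    n = np.linalg.norm(d)
    if n < 1e-9:
        raise DegenerateGeometryError(f"coincident {what} centers")
    return d / n


def pelvis_fixed_axis(r_lhip_pelvis, r_rhip_pelvis) -> np.ndarray:
    """Unit inter-hip axis (left to right hip center), pelvis sensor frame."""
    return _unit_between(r_rhip_pelvis, r_lhip_pelvis, "hip")


def thigh_fixed_axis(r_hip_thigh, r_knee_thigh) -> np.ndarray:
    """Unit knee-to-hip (proximal) axis in the thigh sensor frame."""
    return _unit_between(r_hip_thigh, r_knee_thigh, "hip/knee")


def _orthonormal_frame(first, second, order, what: str) -> np.ndarray:
    """Right-handed frame from a primary axis and an approximate second axis.

    ``order`` gives the column indices for (primary, secondary, tertiary);
    tertiary = primary x secondary is recomputed, and the secondary axis is
    re-orthogonalized so the result is exactly orthonormal.
    """
    p = np.asarray(first, dtype=float)
    p = p / np.linalg.norm(p)
    s = np.asarray(second, dtype=float)
    s = s - np.dot(s, p) * p
    ns = np.linalg.norm(s)
    if ns < 1e-9:
        raise DegeneratePoseError(f"{what}: axes are parallel")
    s = s / ns
    R = np.empty((3, 3))
    i, j, k = order
    R[:, i] = p
    R[:, j] = s
    R[:, k] = np.cross(R[:, (k + 1) % 3], R[:, (k + 2) % 3])
    det = np.linalg.det(R)
    if det < 0:
        raise DegeneratePoseError(
            f"{what}: left-handed frame (check left/right labeling)")
    return R


def build_frames(pelvis_axis, thigh_axis_left, thigh_axis_right,
                 q_left, q_right, still_window=None) -> AnatomicalCalibration:
    """Assemble the anatomical calibration from fixed axes and still-pose
    relative orientations.

    ``pelvis_axis`` (e1) is in the pelvis sensor frame; the thigh axes
    (e3, per side) are in their own thigh sensor frames; ``q_left`` /
    ``q_right`` are the still-pose SSRO quaternions rotating each thigh
    sensor frame into the pelvis sensor frame.
    """
    e1 = np.asarray(pelvis_axis, dtype=float)
    e1 = e1 / np.linalg.norm(e1)
    e2_p = {}
    thigh_frames = {}
    for side, axis, q in (("left", thigh_axis_left, q_left),
                          ("right", thigh_axis_right, q_right)):
        e3_t = np.asarray(axis, dtype=float)
        e3_t = e3_t / np.linalg.norm(e3_t)
        e3 = quat_rotate(np.asarray(q, dtype=float), e3_t)  # in pelvis sensor frame
        if abs(np.dot(e3, e1)) > 1.0 - 1e-9:
            raise DegeneratePoseError(
                f"{side} thigh axis parallel to pelvis axis in still pose")
        e2 = np.cross(e3, e1)
        e2 = e2 / np.linalg.norm(e2)
        e2_p[side] = e2
        # thigh frame: y = e3 (thigh frame), x = this side's e2 rotated back
        e2_t = quat_rotate(np.array([q[0], -q[1], -q[2], -q[3]]), e2)
        # columns (x, y, z) = (e2_t, e3_t, x cross y)
        thigh_frames[side] = _orthonormal_frame(
            e3_t, e2_t, order=(1, 0, 2), what=f"{side} thigh frame")

    x_p = 0.5 * (e2_p["left"] + e2_p["right"])
    nx = np.linalg.norm(x_p)
    if nx < 1e-9:
        raise DegeneratePoseError("left/right floating axes cancel; pelvis X undefined")
    pelvis = _orthonormal_frame(e1, x_p / nx, order=(2, 0, 1), what="pelvis frame")

    return AnatomicalCalibration(
        pelvis_frame=pelvis,
        thigh_frame_left=thigh_frames["left"],
        thigh_frame_right=thigh_frames["right"],
        fixed_axes={
            "pelvis_e1": e1,
            "thigh_e3_left": np.asarray(thigh_axis_left, dtype=float),
            "thigh_e3_right": np.asarray(thigh_axis_right, dtype=float),
            "e2_left_pelvis_frame": e2_p["left"],
            "e2_right_pelvis_frame": e2_p["right"],
        },
        still_window=still_window,
    )


def mean_quaternion(q_trace) -> np.ndarray:
    """Sign-aligned normalized mean of a nearly constant quaternion trace."""
    q = np.asarray(q_trace, dtype=float)
    if q.ndim == 1:
        return q / np.linalg.norm(q)
    ref = q[0]
    signs = np.where(q @ ref < 0, -1.0, 1.0)
    m = (signs[:, None] * q).mean(axis=0)
    return m / np.linalg.norm(m)


def calibrate_from_centers(hip_centers: dict, knee_centers: dict, still_q: dict,
                           still_window=None, sides=("left", "right")
                           ) -> AnatomicalCalibration:
    """Calibration from joint-center results and still-pose orientations.

    ``hip_centers[side]`` is a :class:`~hipkin.joint_center.JointCenterResult`
    for the pelvis(1)-thigh(2) pair; ``knee_centers[side]`` is the knee
    center-to-thigh-sensor vector in the thigh frame (hinge-corrected).
    """
    for side in sides:
        if knee_centers.get(side) is None:
            raise InvalidInputError(
                f"knee center for side {side!r} is required to build the thigh axis")
    # positions of centers = -(center -> sensor vector)
    hip_pos_pelvis = {s: -np.asarray(hip_centers[s].r1, dtype=float) for s in sides}
    e1 = pelvis_fixed_axis(hip_pos_pelvis["left"], hip_pos_pelvis["right"])
    e3 = {}
    for side in sides:
        hip_pos_thigh = -np.asarray(hip_centers[side].r2, dtype=float)
        knee_pos_thigh = -np.asarray(knee_centers[side], dtype=float)
        e3[side] = thigh_fixed_axis(hip_pos_thigh, knee_pos_thigh)
    return build_frames(e1, e3["left"], e3["right"],
                        still_q["left"], still_q["right"],
                        still_window=still_window)
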