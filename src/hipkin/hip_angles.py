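"""3D hip joint angles in the ISB joint coordinate system.

The hip joint coordinate system uses ``e1`` = pelvis Z axis (pointing
right), ``e3`` = thigh y axis (pointing proximally), and the floating axis
``e2 = e3 x e1``.  Flexion/extension (alpha) is the rotation about ``e1``,
internal/external rotation (gamma) about ``e3``, and ad/abduction (beta)
is derived from the angle between ``e1`` and ``e3`` with side-dependent
sign::

    alpha = atan2(eta_a |X x e2|, X . e2),  eta_a = sign((X x e2) . Z)
    gamma = atan2(eta_g |x x e2|, x . e2),  eta_g = sign((x x e2) . -y) (right)
                                            eta_g = sign((x x e2) .  y) (left)
    beta  = -pi/2 + arccos(e1 . e3)  (right)
    beta  = +pi/2 - arccos(e1 . e3)  (left)

This decomposition is equivalent to an intrinsic Z-X-Y rotation sequence;
:func:`joint_rotation_from_angles` provides that forward construction and
is the exact inverse of :func:`hip_angles_at_sample` away from the
``|beta| = 90 deg`` singularity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    InvalidInputError,
    PipelineStageError,
    SingularPoseError,
)
from .rotations import quat_to_matrix

__all__ = [
    "AngleTrace",
    "hip_angles_at_sample",
    "angles_from_joint_rotation",
    "joint_rotation_from_angles",
    "compute_hip_angles",
    "run_pipeline",
]

_SIDES = ("left", "right")


@dataclass
class AngleTrace:
    """Hip angle time series in degrees.

    ``fe`` is flexion(+)/extension(-), ``aa`` ad(+)/abduction(-), and
    ``ier`` internal(+)/external(-) rotation, each in ``(-180, 180]``.
    """

    t: np.ndarray
    fe: np.ndarray
    aa: np.ndarray
    ier: np.ndarray
    side: str
    fs: float

    def __post_init__(self):
        if self.side not in _SIDES:
            raise InvalidInputError(f"side must be one of {_SIDES}")
        n = len(self.t)
        if not (len(self.fe) == len(self.aa) == len(self.ier) == n):
            raise InvalidInputError("angle channels must share one length")

    def __len__(self) -> int:
        return len(self.t)

    def as_array(self) -> np.ndarray:
        return np.column_stack([self.fe, self.aa, self.ier])


def _check_side(side: str):
    if side not in _SIDES:
        raise InvalidInputError(f"side must be one of {_SIDES}, got {side!r}")


def hip_angles_at_sample(pelvis_axes, thigh_axes, side: str):
    """Hip angles (degrees) from axis triads expressed in a common frame.

    ``pelvis_axes`` and ``thigh_axes`` are 3x3 matrices whose *columns* are
    the anatomical axes (pelvis X, Y, Z; thigh x, y, z).
    """
    _check_side(side)
    P = np.asarray(pelvis_axes, dtype=float)
    T = np.asarray(thigh_axes, dtype=float)
    X, Z = P[:, 0], P[:, 2]
    x, y = T[:, 0], T[:, 1]
    e1 = Z
    e3 = y
    d13 = float(np.clip(np.dot(e1, e3), -1.0, 1.0))
    if abs(d13) > 1.0 - 1e-9:
        raise SingularPoseError(
            "thigh long axis parallel to pelvis Z: joint coordinate system singular")
    e2 = np.cross(e3, e1)

    ca = np.cross(X, e2)
    eta_a = np.sign(np.dot(ca, Z)) or 1.0
    alpha = np.arctan2(eta_a * np.linalg.norm(ca), np.dot(X, e2))

    cg = np.cross(x, e2)
    ref = -y if side == "right" else y
    eta_g = np.sign(np.dot(cg, ref)) or 1.0
    gamma = np.arctan2(eta_g * np.linalg.norm(cg), np.dot(x, e2))

    if side == "right":
        beta = -np.pi / 2.0 + np.arccos(d13)
    else:
        beta = np.pi / 2.0 - np.arccos(d13)
    return np.degrees(alpha), np.degrees(beta), np.degrees(gamma)


def angles_from_joint_rotation(R, side: str):
    """Angles from the rotation whose columns are thigh axes in pelvis axes."""
    return hip_angles_at_sample(np.eye(3), np.asarray(R, dtype=float), side)


def _rz(t):
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rx(t):
    c, s = np.cos(t), np.sin(t)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _ry(t):
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def jcs_euler_signs(side: str):
    """Signs (s_beta, s_gamma) mapping (fe, aa, ier) onto the Z-X-Y sequence."""
    _check_side(side)
    return (-1.0, 1.0) if side == "right" else (1.0, -1.0)


def joint_rotation_from_angles(fe_deg: float, aa_deg: float, ier_deg: float,
                               side: str) -> np.ndarray:
    """Forward construction: thigh anatomical axes in the pelvis frame.

    Exactly inverts :func:`angles_from_joint_rotation` for ``|aa| < 90``.
    """
    sb, sg = jcs_euler_signs(side)
    a, b, g = np.radians([fe_deg, aa_deg, ier_deg])
    return _rz(a) @ _rx(sb * b) @ _ry(sg * g)


def compute_hip_angles(calib, q21_trace, side: str,
                       t=None, fs: float | None = None) -> AngleTrace:
    """Angle trace from a calibration and a per-sample SSRO quaternion trace.

    ``q21_trace`` rotates thigh-sensor coordinates into the pelvis-sensor
    frame.  The constant thigh anatomical frame is rotated into the pelvis
    sensor frame at each sample and both triads are then expressed in the
    pelvis anatomical frame before applying the angle formulas.
    """
    _check_side(side)
    q21_trace = np.asarray(q21_trace, dtype=float)
    n = q21_trace.shape[0]
    if t is None:
        if fs is None:
            raise InvalidInputError("provide either t or fs")
        t = np.arange(n) / fs
    t = np.asarray(t, dtype=float)
    fs = fs if fs is not None else 1.0 / np.mean(np.diff(t))

    P = calib.pelvis_frame  # columns X, Y, Z in pelvis sensor frame
    T = calib.thigh_frame(side)  # columns x, y, z in thigh sensor frame
    R21 = quat_to_matrix(q21_trace)  # (N, 3, 3)
    # thigh axes in the pelvis *anatomical* frame, per sample
    thigh_in_anat = np.einsum("ab,nbc,cd->nad", P.T, R21, T)
    fe = np.empty(n)
    aa = np.empty(n)
    ier = np.empty(n)
    eye = np.eye(3)
    for k in range(n):
        try:
            fe[k], aa[k], ier[k] = hip_angles_at_sample(eye, thigh_in_anat[k], side)
        except SingularPoseError as exc:
            raise SingularPoseError(f"{exc} (sample {k})") from exc
    return AngleTrace(t=t, fe=fe, aa=aa, ier=ier, side=side, fs=float(fs))


def run_pipeline(static_trial: dict, dynamic_trial: dict, activity_trial: dict,
                 params=None, sides=("left", "right"), n_min_obs: int = 1500,
                 warmup_s: float = 2.0):
    """End-to-end hip angle estimation from a simulated or recorded protocol.

    Each trial is a mapping from segment name (``pelvis``, ``thigh_left``,
    ``thigh_right``, and optionally ``shank_left``/``shank_right``) to an
    :class:`~hipkin.preprocess.ImuRecording`.  Stages: preprocessing, SSRO
    on every sensor pair, functional joint-center estimation from the
    dynamic trial (hinge-axis corrected knee centers when shank sensors
    are present), anatomical frame construction over the stillest static
    window, and finally angle computation on the activity trial.  The
    first ``warmup_s`` seconds of the dynamic trial are excluded from the
    high-motion sample selection so the filter's initialization transient
    cannot leak into the calibration.

    Returns ``(angles, calibration)`` where ``angles`` maps side to an
    :class:`AngleTrace`.
    """
    from . import alignment, joint_center
    from .preprocess import preprocess_recording
    from .ssro import KFParams, run_ssro

    params = params or KFParams()

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc

    pre = {
        name: {seg: _stage(f"preprocess:{name}:{seg}", preprocess_recording, rec)
               for seg, rec in trial.items()}
        for name, trial in (("static", static_trial),
                            ("dynamic", dynamic_trial),
                            ("activity", activity_trial))
    }

    hip_centers = {}
    knee_centers = {}
    still_q = {}
    activity_q = {}
    for side in sides:
        thigh = f"thigh_{side}"
        shank = f"shank_{side}"

        # SSRO pelvis-thigh on all trials
        sro_dyn = _stage(f"ssro:dynamic:{side}", run_ssro,
                         pre["dynamic"]["pelvis"], pre["dynamic"][thigh], params)
        sro_static = _stage(f"ssro:static:{side}", run_ssro,
                            pre["static"]["pelvis"], pre["static"][thigh], params)
        sro_act = _stage(f"ssro:activity:{side}", run_ssro,
                         pre["activity"]["pelvis"], pre["activity"][thigh], params)
        activity_q[side] = sro_act.q21

        # hip joint center from the dynamic trial (post-warm-up samples)
        k0 = int(round(warmup_s * pre["dynamic"]["pelvis"].fs))

        def _select(rec_a, rec_b):
            idx = joint_center.select_high_motion_samples(
                rec_a.gyro[k0:], rec_b.gyro[k0:], n_min=n_min_obs)
            return idx + k0

        R21 = quat_to_matrix(sro_dyn.q21)
        hip_centers[side] = _stage(
            f"joint_center:hip:{side}", joint_center.estimate_joint_center,
            pre["dynamic"]["pelvis"], pre["dynamic"][thigh], R21,
            indices=_select(pre["dynamic"]["pelvis"], pre["dynamic"][thigh]),
            n_min=n_min_obs)

        # knee joint center from thigh-shank, hinge-axis corrected
        if shank in pre["dynamic"]:
            sro_knee = _stage(f"ssro:knee:{side}", run_ssro,
                              pre["dynamic"][thigh], pre["dynamic"][shank], params)
            Rk = quat_to_matrix(sro_knee.q21)
            knee = _stage(
                f"joint_center:knee:{side}", joint_center.estimate_joint_center,
                pre["dynamic"][thigh], pre["dynamic"][shank], Rk,
                indices=_select(pre["dynamic"][thigh], pre["dynamic"][shank]),
                n_min=n_min_obs)
            axes = _stage(f"hinge_axes:{side}", joint_center.estimate_hinge_axes,
                          pre["dynamic"][thigh].gyro, pre["dynamic"][shank].gyro)
            r1c, _ = joint_center.correct_hinge_center(knee.r1, knee.r2, axes)
            knee_centers[side] = r1c  # knee center -> thigh sensor, thigh frame
        else:
            knee_centers[side] = None

        # still-period mean orientation for frame construction
        window = _stage(f"still_period:{side}", alignment.find_still_period,
                        pre["static"]["pelvis"])
        still_q[side] = alignment.mean_quaternion(sro_static.q21[window[0]:window[1]])

    calib = _stage("build_frames", alignment.calibrate_from_centers,
                   hip_centers, knee_centers, still_q,
                   still_window=window, sides=sides)

    angles = {}
    for side in sides:
        act = pre["activity"]["pelvis"]
        angles[side] = _stage(
            f"angles:{side}", compute_hip_angles,
            calib, activity_q[side], side, t=act.t, fs=act.fs)
    return angles, calib
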