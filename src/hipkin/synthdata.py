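"""Rigid-body MIMU simulator with exact kinematic ground truth.

Two segments joined at a ball (or hinge) joint carry one sensor each at a
fixed offset and mounting rotation.  Joint-angle trajectories are
prescribed as analytic profiles; angular velocity and angular
acceleration are differentiated analytically so the generated gyro,
accelerometer, and magnetometer channels satisfy the rigid-body
joint-center constraint to machine precision before noise is added.
Sensors see gravity, a shared homogeneous world magnetic field, and
optional additive white Gaussian noise per channel.

The :func:`simulate_protocol` convenience reproduces a three-trial study
structure (static standing, multi-plane "star" calibration, periodic
walking-like motion) for a pelvis + two thighs + two shanks sensor set,
which is exactly what the full calibration-and-angles pipeline consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError
from .hip_angles import AngleTrace, jcs_euler_signs
from .joint_center import HingeAxes
from .preprocess import ImuRecording
from .rotations import matrix_to_quat, quat_normalize, quat_to_matrix

__all__ = [
    "Sinusoid",
    "SumProfile",
    "ZERO_PROFILE",
    "NoiseModel",
    "NO_NOISE",
    "ChainGeometry",
    "SimulationOutput",
    "Protocol",
    "simulate_ball_joint",
    "simulate_hinge",
    "simulate_protocol",
    "DEFAULT_NOISE",
    "DEFAULT_MAG_FIELD",
    "GRAVITY",
]

GRAVITY = 9.81
# generic mid-latitude field: unit magnitude, 60 deg downward inclination
DEFAULT_MAG_FIELD = np.array([0.5, 0.0, -np.sqrt(3.0) / 2.0])
_G_WORLD = np.array([0.0, 0.0, -GRAVITY])


@dataclass(frozen=True)
class Sinusoid:
    """Analytic profile ``offset + amp * sin(2 pi f t + phase)``."""

    amp: float = 0.0
    freq: float = 0.0
    phase: float = 0.0
    offset: float = 0.0

    def value(self, t):
        return self.offset + self.amp * np.sin(2 * np.pi * self.freq * t + self.phase)

    def d1(self, t):
        w = 2 * np.pi * self.freq
        return self.amp * w * np.cos(w * t + self.phase)

    def d2(self, t):
        w = 2 * np.pi * self.freq
        return -self.amp * w * w * np.sin(w * t + self.phase)

    def scaled(self, factor: float) -> "Sinusoid":
        return Sinusoid(self.amp * factor, self.freq, self.phase,
                        self.offset * factor)


@dataclass(frozen=True)
class SumProfile:
    """Sum of analytic component profiles (e.g. sweep + tremor)."""

    components: tuple

    def value(self, t):
        return sum(c.value(t) for c in self.components)

    def d1(self, t):
        return sum(c.d1(t) for c in self.components)

    def d2(self, t):
        return sum(c.d2(t) for c in self.components)

    def scaled(self, factor: float) -> "SumProfile":
        return SumProfile(tuple(c.scaled(factor) for c in self.components))


ZERO_PROFILE = Sinusoid()


@dataclass(frozen=True)
class NoiseModel:
    """Per-channel additive white Gaussian noise standard deviations."""

    gyro: float = 0.005   # rad/s
    accel: float = 0.08   # m/s^2
    mag: float = 0.01     # same units as the (unit) world field

    def __post_init__(self):
        for name in ("gyro", "accel", "mag"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"noise sigma {name} must be >= 0")


DEFAULT_NOISE = NoiseModel()
NO_NOISE = NoiseModel(0.0, 0.0, 0.0)


@dataclass
class ChainGeometry:
    """Sensor placement for one two-segment chain.

    ``r1`` / ``r2`` are the joint-center-to-sensor-origin vectors in each
    *sensor* frame (m); ``mount1`` / ``mount2`` are unit quaternions
    rotating sensor coordinates into the segment frame.
    """

    r1: np.ndarray
    r2: np.ndarray
    mount1: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0, 0]))
    mount2: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0, 0]))
    hinge_axis: np.ndarray | None = None

    def __post_init__(self):
        self.r1 = np.asarray(self.r1, dtype=float)
        self.r2 = np.asarray(self.r2, dtype=float)
        self.mount1 = quat_normalize(self.mount1)
        self.mount2 = quat_normalize(self.mount2)
        if self.hinge_axis is not None:
            a = np.asarray(self.hinge_axis, dtype=float)
            self.hinge_axis = a / np.linalg.norm(a)


@dataclass
class SimulationOutput:
    """Recordings plus exact (pre-noise) ground truth for one sensor pair."""

    imu1: ImuRecording
    imu2: ImuRecording
    truth_q21: np.ndarray          # (N, 4) sensor-2 -> sensor-1 quaternion
    truth_angles: AngleTrace
    truth_geometry: ChainGeometry
    seed: int | None
    clean_imu1: ImuRecording = None
    clean_imu2: ImuRecording = None
    wdot1: np.ndarray = None       # exact angular acceleration, sensor-1 frame
    wdot2: np.ndarray = None
    truth_axes: HingeAxes | None = None


@dataclass
class Protocol:
    """Bundle of simulated trials mirroring a static + star + walking study."""

    trials: dict                  # trial name -> {segment name -> ImuRecording}
    truth_angles: dict            # trial name -> {side -> AngleTrace}
    truth_q21: dict               # trial name -> {side -> (N, 4)}
    geometry: dict                # side -> {"hip": ChainGeometry, "knee": ChainGeometry}
    mounts: dict                  # segment name -> quaternion
    fs: float
    seed: int


# ---------------------------------------------------------------------------
# analytic kinematics
# ---------------------------------------------------------------------------

def _zxy_kinematics(t, p1: Sinusoid, p2: Sinusoid, p3: Sinusoid):
    """Rotation, body angular velocity, and body angular acceleration of an
    intrinsic Z-X-Y Euler-angle profile (angles in radians)."""
    th1, th2, th3 = p1.value(t), p2.value(t), p3.value(t)
    d1, d2, d3 = p1.d1(t), p2.d1(t), p3.d1(t)
    a1, a2, a3 = p1.d2(t), p2.d2(t), p3.d2(t)
    c1, s1 = np.cos(th1), np.sin(th1)
    c2, s2 = np.cos(th2), np.sin(th2)
    c3, s3 = np.cos(th3), np.sin(th3)

    n = len(np.atleast_1d(th1))
    R = np.empty((n, 3, 3))
    # R = Rz(th1) Rx(th2) Ry(th3)
    R[:, 0, 0] = c1 * c3 - s1 * s2 * s3
    R[:, 0, 1] = -s1 * c2
    R[:, 0, 2] = c1 * s3 + s1 * s2 * c3
    R[:, 1, 0] = s1 * c3 + c1 * s2 * s3
    R[:, 1, 1] = c1 * c2
    R[:, 1, 2] = s1 * s3 - c1 * s2 * c3
    R[:, 2, 0] = -c2 * s3
    R[:, 2, 1] = s2
    R[:, 2, 2] = c2 * c3

    # body-frame axis columns of the Euler-rate map
    col1 = np.stack([-s3 * c2, s2, c3 * c2], axis=-1)
    col2 = np.stack([c3, np.zeros_like(c3), s3], axis=-1)
    col3 = np.stack([np.zeros_like(c3), np.ones_like(c3), np.zeros_like(c3)], axis=-1)
    w = d1[:, None] * col1 + d2[:, None] * col2 + d3[:, None] * col3

    dcol1 = np.stack([-c3 * d3 * c2 + s3 * s2 * d2,
                      c2 * d2,
                      -s3 * d3 * c2 - c3 * s2 * d2], axis=-1)
    dcol2 = np.stack([-s3 * d3, np.zeros_like(c3), c3 * d3], axis=-1)
    wd = (a1[:, None] * col1 + a2[:, None] * col2 + a3[:, None] * col3
          + d1[:, None] * dcol1 + d2[:, None] * dcol2)
    return R, w, wd


def _axis_angle_kinematics(t, axis, profile: Sinusoid):
    """Rotation about a fixed axis with analytic rate and acceleration."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    th = profile.value(t)
    d = profile.d1(t)
    a = profile.d2(t)
    c, s = np.cos(th), np.sin(th)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    K2 = K @ K
    n = len(np.atleast_1d(th))
    R = (np.eye(3)[None] + s[:, None, None] * K[None]
         + (1 - c)[:, None, None] * K2[None])
    w = d[:, None] * axis[None]
    wd = a[:, None] * axis[None]
    return R, w, wd


@dataclass
class _SegmentMotion:
    """World orientation, body rates, and world origin acceleration."""

    R: np.ndarray          # (N, 3, 3) segment -> world
    w: np.ndarray          # (N, 3) angular velocity, segment frame
    wd: np.ndarray         # (N, 3) angular acceleration, segment frame
    acc: np.ndarray        # (N, 3) world-frame acceleration of segment origin


def _static_motion(n):
    return _SegmentMotion(R=np.broadcast_to(np.eye(3), (n, 3, 3)).copy(),
                          w=np.zeros((n, 3)), wd=np.zeros((n, 3)),
                          acc=np.zeros((n, 3)))


def _base_motion(t, euler=None, translation=None) -> _SegmentMotion:
    n = len(t)
    if euler is None:
        m = _static_motion(n)
    else:
        R, w, wd = _zxy_kinematics(t, *euler)
        m = _SegmentMotion(R=R, w=w, wd=wd, acc=np.zeros((n, 3)))
    if translation is not None:
        m.acc = np.stack([p.d2(t) for p in translation], axis=-1)
    return m


def _child_motion(parent: _SegmentMotion, offset, RJ, wJ, wdJ) -> _SegmentMotion:
    """Motion of a child segment attached at ``offset`` (parent frame)."""
    offset = np.asarray(offset, dtype=float)
    R = parent.R @ RJ
    RJt_w = np.einsum("nij,nj->ni", np.swapaxes(RJ, 1, 2), parent.w)
    w = RJt_w + wJ
    RJt_wd = np.einsum("nij,nj->ni", np.swapaxes(RJ, 1, 2), parent.wd)
    wd = RJt_wd - np.cross(wJ, RJt_w) + wdJ
    # centripetal + tangential acceleration of the joint point
    local = (np.cross(parent.wd, offset[None]) +
             np.cross(parent.w, np.cross(parent.w, offset[None])))
    acc = parent.acc + np.einsum("nij,nj->ni", parent.R, local)
    return _SegmentMotion(R=R, w=w, wd=wd, acc=acc)


def _sensor_channels(motion: _SegmentMotion, mount_q, s_pos, mag_world):
    """Exact gyro/accel/mag channels plus angular acceleration, sensor frame."""
    M = quat_to_matrix(mount_q)
    s_pos = np.asarray(s_pos, dtype=float)
    gyro = motion.w @ M
    wdot = motion.wd @ M
    spin = (np.cross(motion.wd, s_pos[None]) +
            np.cross(motion.w, np.cross(motion.w, s_pos[None])))
    seg_accel = np.einsum("nji,nj->ni", motion.R, motion.acc - _G_WORLD[None]) + spin
    accel = seg_accel @ M
    mag = np.einsum("nji,j->ni", motion.R, mag_world) @ M
    return gyro, accel, mag, wdot


def _make_recordings(t, fs, chans1, chans2, noise: NoiseModel | None, rng):
    noise = noise or NO_NOISE

    def build(chans, add_noise):
        gyro, accel, mag = (c.copy() for c in chans)
        if add_noise:
            gyro += rng.normal(0.0, noise.gyro, gyro.shape) if noise.gyro else 0.0
            accel += rng.normal(0.0, noise.accel, accel.shape) if noise.accel else 0.0
            mag += rng.normal(0.0, noise.mag, mag.shape) if noise.mag else 0.0
        return ImuRecording(t=t.copy(), gyro=gyro, accel=accel, mag=mag, fs=fs)

    clean1 = build(chans1, False)
    clean2 = build(chans2, False)
    noisy1 = build(chans1, True)
    noisy2 = build(chans2, True)
    return noisy1, noisy2, clean1, clean2


def _relative_quat_trace(R1, R2):
    """Sign-continuous quaternion trace of R1' R2."""
    R21 = np.einsum("nji,njk->nik", R1, R2)
    out = np.empty((len(R21), 4))
    for k, R in enumerate(R21):
        q = matrix_to_quat(R)
        if k > 0 and np.dot(q, out[k - 1]) < 0:
            q = -q
        out[k] = q
    return out


def _time_grid(fs: float, duration: float):
    n = int(round(duration * fs))
    if n < 2:
        raise InvalidParameterError("duration * fs must be at least 2 samples")
    return np.arange(n) / fs


# ---------------------------------------------------------------------------
# public simulators
# ---------------------------------------------------------------------------

def simulate_ball_joint(profiles, geometry: ChainGeometry, fs: float = 128.0,
                        duration: float = 10.0, noise: NoiseModel | None = None,
                        mag_field=DEFAULT_MAG_FIELD, seed: int | None = 0,
                        side: str = "right", base_euler=None,
                        base_translation=None) -> SimulationOutput:
    """Simulate a two-sensor chain articulated by a ball joint.

    ``profiles`` is a triple of :class:`Sinusoid` (degrees) prescribing the
    (FE, AA, IER) joint angles of ``side``.  ``base_euler`` optionally
    prescribes proximal-segment world orientation (three radian profiles,
    Z-X-Y), and ``base_translation`` a world translation of the joint
    center (three metre profiles).
    """
    t = _time_grid(fs, duration)
    rng = np.random.default_rng(seed)
    pfe, paa, pier = profiles
    sb, sg = jcs_euler_signs(side)
    d2r = np.pi / 180.0
    RJ, wJ, wdJ = _zxy_kinematics(t, pfe.scaled(d2r), paa.scaled(sb * d2r),
                                  pier.scaled(sg * d2r))
    parent = _base_motion(t, base_euler, base_translation)
    child = _child_motion(parent, np.zeros(3), RJ, wJ, wdJ)

    M1 = quat_to_matrix(geometry.mount1)
    M2 = quat_to_matrix(geometry.mount2)
    chans1 = _sensor_channels(parent, geometry.mount1, M1 @ geometry.r1, mag_field)
    chans2 = _sensor_channels(child, geometry.mount2, M2 @ geometry.r2, mag_field)
    imu1, imu2, clean1, clean2 = _make_recordings(
        t, fs, chans1[:3], chans2[:3], noise, rng)

    q21 = _relative_quat_trace(parent.R @ M1, child.R @ M2)
    truth = AngleTrace(t=t, fe=pfe.value(t) * np.ones_like(t),
                       aa=paa.value(t) * np.ones_like(t),
                       ier=pier.value(t) * np.ones_like(t), side=side, fs=fs)
    return SimulationOutput(imu1=imu1, imu2=imu2, truth_q21=q21,
                            truth_angles=truth, truth_geometry=geometry,
                            seed=seed, clean_imu1=clean1, clean_imu2=clean2,
                            wdot1=chans1[3], wdot2=chans2[3])


def simulate_hinge(angle_profile: Sinusoid, axis, geometry: ChainGeometry,
                   fs: float = 128.0, duration: float = 10.0,
                   noise: NoiseModel | None = None, mag_field=DEFAULT_MAG_FIELD,
                   seed: int | None = 0, base_euler=None,
                   base_translation=None) -> SimulationOutput:
    """Simulate a 1-DoF hinge joint (angle profile in degrees, axis in the
    proximal segment frame).  Ground truth includes the hinge axis in both
    sensor frames."""
    t = _time_grid(fs, duration)
    rng = np.random.default_rng(seed)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    RJ, wJ, wdJ = _axis_angle_kinematics(t, axis,
                                         angle_profile.scaled(np.pi / 180.0))
    parent = _base_motion(t, base_euler, base_translation)
    child = _child_motion(parent, np.zeros(3), RJ, wJ, wdJ)

    M1 = quat_to_matrix(geometry.mount1)
    M2 = quat_to_matrix(geometry.mount2)
    chans1 = _sensor_channels(parent, geometry.mount1, M1 @ geometry.r1, mag_field)
    chans2 = _sensor_channels(child, geometry.mount2, M2 @ geometry.r2, mag_field)
    imu1, imu2, clean1, clean2 = _make_recordings(
        t, fs, chans1[:3], chans2[:3], noise, rng)

    q21 = _relative_quat_trace(parent.R @ M1, child.R @ M2)
    truth = AngleTrace(t=t, fe=angle_profile.value(t) * np.ones_like(t),
                       aa=np.zeros_like(t), ier=np.zeros_like(t),
                       side="right", fs=fs)
    geometry = ChainGeometry(r1=geometry.r1, r2=geometry.r2,
                             mount1=geometry.mount1, mount2=geometry.mount2,
                             hinge_axis=axis)
    axes = HingeAxes(j1=M1.T @ axis, j2=M2.T @ axis)
    return SimulationOutput(imu1=imu1, imu2=imu2, truth_q21=q21,
                            truth_angles=truth, truth_geometry=geometry,
                            seed=seed, clean_imu1=clean1, clean_imu2=clean2,
                            wdot1=chans1[3], wdot2=chans2[3], truth_axes=axes)


def joint_constraint_residual(sim: SimulationOutput) -> float:
    """Max violation of the ball-joint acceleration identity on clean data."""
    from .rotations import skew
    g = sim.truth_geometry
    R21 = quat_to_matrix(sim.truth_q21)
    worst = 0.0
    for k in range(len(sim.clean_imu1)):
        K1 = (skew(sim.clean_imu1.gyro[k]) @ skew(sim.clean_imu1.gyro[k])
              + skew(sim.wdot1[k]))
        K2 = (skew(sim.clean_imu2.gyro[k]) @ skew(sim.clean_imu2.gyro[k])
              + skew(sim.wdot2[k]))
        lhs = sim.clean_imu1.accel[k] - K1 @ g.r1
        rhs = R21[k] @ (sim.clean_imu2.accel[k] - K2 @ g.r2)
        worst = max(worst, float(np.max(np.abs(lhs - rhs))))
    return worst


# ---------------------------------------------------------------------------
# study protocol
# ---------------------------------------------------------------------------

# segment-frame geometry (ISB axes: x anterior, y proximal/up, z right), metres
_HIP_OFFSET = {"left": np.array([0.0, 0.0, -0.09]),
               "right": np.array([0.0, 0.0, 0.09])}
_PELVIS_SENSOR = np.array([-0.10, 0.05, 0.0])      # posterior lumbar
_THIGH_SENSOR = {"left": np.array([0.02, -0.25, -0.06]),
                 "right": np.array([0.02, -0.25, 0.06])}
_KNEE_OFFSET = np.array([0.0, -0.42, 0.0])          # knee center in thigh frame
_SHANK_SENSOR = {"left": np.array([0.04, -0.12, 0.06]),
                 "right": np.array([0.04, -0.12, -0.06])}
_KNEE_AXIS = np.array([0.0, 0.0, 1.0])              # FE axis, thigh frame

STAR_DURATION_S = 55.0
WALKING_DURATION_S = 60.0
STATIC_DURATION_S = 30.0


def _hip_profiles(trial: str, side: str):
    """Prescribed hip angle profiles (degrees) per trial and side."""
    lag = 0.0 if side == "right" else np.pi
    if trial == "static":
        return (ZERO_PROFILE, ZERO_PROFILE, ZERO_PROFILE)
    if trial == "star":
        # slow multi-plane sweeps with a quick low-amplitude oscillation on
        # top: the sweeps exercise the full range while the oscillation adds
        # the angular-acceleration richness functional calibration relies on
        return (SumProfile((Sinusoid(35.0, 0.2, lag), Sinusoid(10.0, 1.4, 0.4 + lag))),
                SumProfile((Sinusoid(20.0, 0.15, 1.0 + lag),
                            Sinusoid(8.0, 1.7, 1.2 + lag))),
                SumProfile((Sinusoid(15.0, 0.25, 2.0 + lag),
                            Sinusoid(8.0, 1.2, 2.2 + lag))))
    if trial == "walking":
        return (Sinusoid(30.0, 1.0, lag), Sinusoid(8.0, 1.0, np.pi / 2 + lag),
                Sinusoid(8.0, 1.0, np.pi + lag))
    raise InvalidParameterError(f"unknown trial {trial!r}")


def _knee_profile(trial: str, side: str) -> Sinusoid:
    lag = 0.0 if side == "right" else np.pi
    if trial == "static":
        return ZERO_PROFILE
    if trial == "star":
        return SumProfile((Sinusoid(25.0, 0.41, lag, offset=-30.0),
                           Sinusoid(8.0, 1.5, 0.3 + lag)))
    return Sinusoid(20.0, 1.0, lag + 0.5, offset=-25.0)


def _pelvis_base(trial: str):
    """Pelvis world-orientation (radians) and translation (m) profiles."""
    if trial == "static":
        return None, None
    deg = np.pi / 180.0
    if trial == "star":
        euler = (SumProfile((Sinusoid(8.0 * deg, 0.3), Sinusoid(4.0 * deg, 1.3, 0.5))),
                 SumProfile((Sinusoid(6.0 * deg, 0.23, 0.8),
                             Sinusoid(4.0 * deg, 1.6, 1.1))),
                 SumProfile((Sinusoid(6.0 * deg, 0.13, 1.5),
                             Sinusoid(4.0 * deg, 1.1, 1.9))))
        return euler, None
    euler = (Sinusoid(3.0 * deg, 1.0, 0.3), Sinusoid(2.0 * deg, 2.0, 0.9),
             Sinusoid(3.0 * deg, 1.0, 1.7))
    trans = (Sinusoid(0.01, 1.0), Sinusoid(0.015, 2.0, 0.5), Sinusoid(0.0, 0.0))
    return euler, trans


def _random_mount(rng) -> np.ndarray:
    q = rng.normal(size=4)
    return quat_normalize(q)


def simulate_protocol(seed: int = 0, fs: float = 128.0,
                      noise: NoiseModel | None = DEFAULT_NOISE,
                      randomize_mounts: bool = True,
                      mag_field=DEFAULT_MAG_FIELD) -> Protocol:
    """Simulate the full three-trial study for five sensors.

    Trials: 30 s static standing, 55 s multi-plane star-like hip motion
    (with knee flexion), and 60 s periodic walking-like motion at 1 Hz.
    The pelvis sensor recording is shared by both sides; mounting
    rotations are randomized per sensor (seeded) unless disabled.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    segs = ["pelvis", "thigh_left", "thigh_right", "shank_left", "shank_right"]
    if randomize_mounts:
        mounts = {s: _random_mount(rng) for s in segs}
    else:
        mounts = {s: np.array([1.0, 0.0, 0.0, 0.0]) for s in segs}
    mount_R = {s: quat_to_matrix(mounts[s]) for s in segs}

    geometry = {}
    for side in ("left", "right"):
        hip = ChainGeometry(
            r1=mount_R["pelvis"].T @ (_PELVIS_SENSOR - _HIP_OFFSET[side]),
            r2=mount_R[f"thigh_{side}"].T @ _THIGH_SENSOR[side],
            mount1=mounts["pelvis"], mount2=mounts[f"thigh_{side}"])
        knee = ChainGeometry(
            r1=mount_R[f"thigh_{side}"].T @ (_THIGH_SENSOR[side] - _KNEE_OFFSET),
            r2=mount_R[f"shank_{side}"].T @ _SHANK_SENSOR[side],
            mount1=mounts[f"thigh_{side}"], mount2=mounts[f"shank_{side}"],
            hinge_axis=_KNEE_AXIS)
        geometry[side] = {"hip": hip, "knee": knee}

    durations = {"static": STATIC_DURATION_S, "star": STAR_DURATION_S,
                 "walking": WALKING_DURATION_S}
    trials = {}
    truth_angles = {}
    truth_q21 = {}
    noise = noise or NO_NOISE
    for trial, dur in durations.items():
        t = _time_grid(fs, dur)
        euler, trans = _pelvis_base(trial)
        pelvis_motion = _base_motion(t, euler, trans)
        chans = {}
        chans["pelvis"] = _sensor_channels(
            pelvis_motion, mounts["pelvis"], _PELVIS_SENSOR, mag_field)
        truth_angles[trial] = {}
        truth_q21[trial] = {}
        d2r = np.pi / 180.0
        for side in ("left", "right"):
            pfe, paa, pier = _hip_profiles(trial, side)
            sb, sg = jcs_euler_signs(side)
            RJ, wJ, wdJ = _zxy_kinematics(t, pfe.scaled(d2r),
                                          paa.scaled(sb * d2r),
                                          pier.scaled(sg * d2r))
            thigh_motion = _child_motion(pelvis_motion, _HIP_OFFSET[side],
                                         RJ, wJ, wdJ)
            kp = _knee_profile(trial, side)
            RK, wK, wdK = _axis_angle_kinematics(t, _KNEE_AXIS, kp.scaled(d2r))
            shank_motion = _child_motion(thigh_motion, _KNEE_OFFSET, RK, wK, wdK)

            chans[f"thigh_{side}"] = _sensor_channels(
                thigh_motion, mounts[f"thigh_{side}"], _THIGH_SENSOR[side],
                mag_field)
            chans[f"shank_{side}"] = _sensor_channels(
                shank_motion, mounts[f"shank_{side}"], _SHANK_SENSOR[side],
                mag_field)

            truth_angles[trial][side] = AngleTrace(
                t=t, fe=pfe.value(t) * np.ones_like(t),
                aa=paa.value(t) * np.ones_like(t),
                ier=pier.value(t) * np.ones_like(t), side=side, fs=fs)
            truth_q21[trial][side] = _relative_quat_trace(
                pelvis_motion.R @ mount_R["pelvis"],
                thigh_motion.R @ mount_R[f"thigh_{side}"])

        recs = {}
        for seg in segs:
            gyro, accel, mag, _ = chans[seg]
            gyro = gyro + (rng.normal(0.0, noise.gyro, gyro.shape)
                           if noise.gyro else 0.0)
            accel = accel + (rng.normal(0.0, noise.accel, accel.shape)
                             if noise.accel else 0.0)
            mag = mag + (rng.normal(0.0, noise.mag, mag.shape)
                         if noise.mag else 0.0)
            recs[seg] = ImuRecording(t=t.copy(), gyro=gyro, accel=accel,
                                     mag=mag, fs=fs)
        trials[trial] = recs

    return Protocol(trials=trials, truth_angles=truth_angles,
                    truth_q21=truth_q21, geometry=geometry, mounts=mounts,
                    fs=fs, seed=seed)
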