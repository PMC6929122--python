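"""Sensor-to-sensor relative orientation (SSRO) Kalman filter.

Estimates, from two time-synchronized MIMUs on adjacent body segments, the
unit quaternion ``q21`` rotating sensor-2 coordinates into the sensor-1
frame, together with the gravity direction in each sensor frame.  The
10-element state is ``chi = [g1; g2; q21]`` with covariance ``P``.

Model summary
-------------
Time update (first order, gyro-driven)::

    g_i  <- (I3 - dt [w_i x]) g_i
    q21  <- (I4 - dt/2 Omega(w_diff)) q21,   w_diff = w2 - R21' w1

with process noise built from the gyro noise variance.  Measurements are
(a) the gravity direction from the accelerometer after subtracting an
AR(1) prediction of the true (non-gravitational) acceleration, and (b) a
direct quaternion measurement built by aligning the gravity estimates and
the gravity-orthogonal (horizontal) magnetic-field components of the two
sensors.  Because the magnetic field only ever enters as the *shared*
field seen by both sensors, homogeneous magnetic disturbances cancel.

True acceleration is recovered after each update as ``a_i - G g_i`` and
drives both the AR(1) gravity measurement and the adaptive measurement
noise: the quaternion measurement is de-weighted in proportion to the
current body acceleration.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .exceptions import (
    DegenerateHeadingError,
    InitializationError,
    InvalidInputError,
    InvalidParameterError,
    NumericalError,
)
from .preprocess import ImuRecording
from .rotations import (
    quat_from_two_vectors,
    quat_multiply,
    quat_normalize,
    quat_operator_matrix,
    quat_rotate,
    quat_to_matrix,
    skew,
)

__all__ = [
    "KFParams",
    "KFState",
    "SsroResult",
    "initialize",
    "time_update",
    "gravity_measurement",
    "quaternion_measurement",
    "measurement_noise",
    "run_ssro",
]


@dataclass
class KFParams:
    """SSRO filter parameters.

    Defaults are the values tuned for Opal MIMUs on a stationary surface:
    gyro noise parameter 1e-3, accelerometer noise parameter 6e-3 (the
    covariance expressions use their squares), AR(1) constant 0.003,
    moving-average window 64 samples, and quaternion measurement error
    factor 5e-8.  With these values the quaternion estimate leans on gyro
    integration during dynamics and on the gravity/magnetic measurement
    when body acceleration is small.
    """

    sigma_w: float = 1e-3      # gyro noise parameter (squared in Q)
    sigma_a: float = 6e-3      # accelerometer noise parameter (squared in M)
    c: float = 0.003           # AR(1) constant of the true-acceleration model
    n_ma: int = 64             # moving-average window, samples
    mu: float = 5e-8           # quaternion measurement error factor
    g: float = 9.81            # gravitational acceleration, m/s^2
    p0: float = 1e-2           # initial state covariance scale
    n_init: int | None = None  # init window; defaults to n_ma

    def __post_init__(self):
        if not (0.0 < self.c < 1.0):
            raise InvalidParameterError("c must lie in (0, 1)")
        if self.n_ma < 1:
            raise InvalidParameterError("n_ma must be >= 1")
        for name in ("sigma_w", "sigma_a", "mu", "g", "p0"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "KFParams":
        return cls(**{k: d[k] for k in d})

    @classmethod
    def from_yaml(cls, path) -> "KFParams":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return {"sigma_w": self.sigma_w, "sigma_a": self.sigma_a, "c": self.c,
                "n_ma": self.n_ma, "mu": self.mu, "g": self.g, "p0": self.p0}


@dataclass
class KFState:
    """Filter state: gravity directions, relative quaternion, covariance."""

    g1: np.ndarray
    g2: np.ndarray
    q21: np.ndarray
    P: np.ndarray
    a_tilde1: np.ndarray = field(default_factory=lambda: np.zeros(3))
    a_tilde2: np.ndarray = field(default_factory=lambda: np.zeros(3))
    hist1: deque = field(default_factory=deque)
    hist2: deque = field(default_factory=deque)

    @property
    def chi(self) -> np.ndarray:
        return np.concatenate([self.g1, self.g2, self.q21])


@dataclass
class SsroResult:
    """Per-sample SSRO output traces (same length as the input recordings)."""

    t: np.ndarray
    q21: np.ndarray       # (N, 4)
    g1: np.ndarray        # (N, 3)
    g2: np.ndarray        # (N, 3)
    a_tilde1: np.ndarray  # (N, 3)
    a_tilde2: np.ndarray  # (N, 3)
    P: np.ndarray | None = None  # (N, 10, 10) when requested


def gravity_measurement(a_k, a_tilde_prev, c: float, G: float):
    """Gravity-direction measurement ``zeta_g = a_k - c a~_{k-1}``, H = G I3."""
    a_k = np.asarray(a_k, dtype=float)
    a_tilde_prev = np.asarray(a_tilde_prev, dtype=float)
    return a_k - c * a_tilde_prev, G * np.eye(3)


def quaternion_measurement(g1_hat, g2_hat, m1, m2) -> np.ndarray:
    """Direct quaternion measurement from gravity and magnetic field pairs.

    First rotates ``g2_hat`` onto ``g1_hat`` (partial alignment), then
    closes the remaining heading rotation by aligning the
    gravity-orthogonal magnetic components.  Raises
    :class:`DegenerateHeadingError` when either horizontal magnetic
    component vanishes (field parallel to gravity).
    """
    g1_hat = np.asarray(g1_hat, dtype=float)
    g2_hat = np.asarray(g2_hat, dtype=float)
    g1_hat = g1_hat / np.linalg.norm(g1_hat)
    g2_hat = g2_hat / np.linalg.norm(g2_hat)
    q_2d = quat_from_two_vectors(g2_hat, g1_hat)

    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    mxy1 = m1 - np.dot(m1, g1_hat) * g1_hat
    mxy2 = m2 - np.dot(m2, g2_hat) * g2_hat
    n1 = np.linalg.norm(mxy1)
    n2 = np.linalg.norm(mxy2)
    scale = max(np.linalg.norm(m1), np.linalg.norm(m2), 1e-30)
    if n1 < 1e-9 * scale or n2 < 1e-9 * scale:
        raise DegenerateHeadingError(
            "magnetic field parallel to gravity: heading unobservable")
    m2_rot = quat_rotate(q_2d, mxy2 / n2)
    if np.dot(m2_rot, mxy1 / n1) < -1.0 + 1e-8:
        # heading misaligned by half a turn: both vectors lie in the plane
        # orthogonal to g1, so the rotation axis is the gravity direction
        q_d1 = np.concatenate([[0.0], g1_hat])
    else:
        q_d1 = quat_from_two_vectors(m2_rot, mxy1 / n1)
    return quat_multiply(q_d1, q_2d)


def measurement_noise(hist1, hist2, params: KFParams) -> np.ndarray:
    """Adaptive 10x10 measurement noise covariance.

    Per-sensor gravity block: ``sigma_a^2 I3 + (c^2 / N) sum a~ a~'`` over
    the recent true-acceleration history (window grows to ``n_ma``).
    Quaternion block: ``mu (|a~1|^2 + |a~2|^2) I4`` using the most recent
    true-acceleration estimates (zero when the history is empty, so the
    first update trusts the quaternion measurement fully).
    """
    M = np.zeros((10, 10))
    for sl, hist in (((0, 3), hist1), ((3, 6), hist2)):
        block = params.sigma_a ** 2 * np.eye(3)
        if len(hist) > 0:
            acc = np.zeros((3, 3))
            for a in hist:
                acc += np.outer(a, a)
            block = block + (params.c ** 2 / len(hist)) * acc
        M[sl[0]:sl[1], sl[0]:sl[1]] = block
    a1 = hist1[-1] if len(hist1) else np.zeros(3)
    a2 = hist2[-1] if len(hist2) else np.zeros(3)
    M[6:, 6:] = params.mu * (np.dot(a1, a1) + np.dot(a2, a2)) * np.eye(4)
    return M


def initialize(imu1: ImuRecording, imu2: ImuRecording, params: KFParams) -> KFState:
    """Initialize the state from the first ``n_init`` samples.

    Gravity directions come from the normalized mean accelerometer reading;
    the quaternion from the direct measurement built on those vectors and
    the mean magnetic fields.
    """
    if abs(imu1.fs - imu2.fs) > 1e-9 or len(imu1) != len(imu2):
        raise InvalidInputError("recordings must be synchronized at the same rate")
    n_init = params.n_init if params.n_init is not None else params.n_ma
    n_init = min(n_init, len(imu1))
    a1 = imu1.accel[:n_init].mean(axis=0)
    a2 = imu2.accel[:n_init].mean(axis=0)
    if np.linalg.norm(a1) < 1e-3 * params.g or np.linalg.norm(a2) < 1e-3 * params.g:
        raise InitializationError(
            "mean initial acceleration is near zero (free fall?); cannot "
            "initialize gravity directions")
    g1 = a1 / np.linalg.norm(a1)
    g2 = a2 / np.linalg.norm(a2)
    m1 = imu1.mag[:n_init].mean(axis=0)
    m2 = imu2.mag[:n_init].mean(axis=0)
    q21 = quaternion_measurement(g1, g2, m1, m2)
    return KFState(g1=g1, g2=g2, q21=q21, P=params.p0 * np.eye(10),
                   hist1=deque(maxlen=params.n_ma), hist2=deque(maxlen=params.n_ma))


def _state_update_matrices(state: KFState, w1, w2, dt: float, params: KFParams):
    """Block-diagonal A and Q for one prediction step."""
    R21 = quat_to_matrix(state.q21)
    w_diff = w2 - R21.T @ w1
    Ag1 = np.eye(3) - dt * skew(w1)
    Ag2 = np.eye(3) - dt * skew(w2)
    Aq = np.eye(4) - 0.5 * dt * quat_operator_matrix(np.concatenate([[0.0], w_diff]))
    A = np.zeros((10, 10))
    A[0:3, 0:3] = Ag1
    A[3:6, 3:6] = Ag2
    A[6:10, 6:10] = Aq

    # Q_g = dt^2 s_w^2 [g x][g x]' ; Q_q = dt^2 s_w^2 Mq Mq' = dt^2 s_w^2 I4
    sw2 = params.sigma_w ** 2
    Q = np.zeros((10, 10))
    S1 = skew(state.g1)
    S2 = skew(state.g2)
    Q[0:3, 0:3] = dt * dt * sw2 * (S1 @ S1.T)
    Q[3:6, 3:6] = dt * dt * sw2 * (S2 @ S2.T)
    Mq = quat_operator_matrix(state.q21)
    Q[6:10, 6:10] = dt * dt * sw2 * (Mq @ Mq.T)
    return A, Q


def time_update(state: KFState, w1, w2, dt: float, params: KFParams) -> KFState:
    """Gyro-driven prediction of the state and covariance (one step)."""
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if not (np.all(np.isfinite(w1)) and np.all(np.isfinite(w2))):
        raise InvalidInputError("non-finite angular velocity")
    A, Q = _state_update_matrices(state, w1, w2, dt, params)
    chi = A @ state.chi
    P = A @ state.P @ A.T + Q
    g1 = chi[0:3] / np.linalg.norm(chi[0:3])
    g2 = chi[3:6] / np.linalg.norm(chi[3:6])
    q21 = quat_normalize(chi[6:10])
    return KFState(g1=g1, g2=g2, q21=q21, P=0.5 * (P + P.T),
                   a_tilde1=state.a_tilde1, a_tilde2=state.a_tilde2,
                   hist1=state.hist1, hist2=state.hist2)


def _observation_matrix(G: float) -> np.ndarray:
    H = np.eye(10)
    H[0:6, 0:6] *= G
    return H


def run_ssro(imu1: ImuRecording, imu2: ImuRecording,
             params: KFParams | None = None,
             return_covariance: bool = False) -> SsroResult:
    """Run the full predict/update SSRO cycle over two recordings.

    Sample 0 carries the initialization values; every subsequent sample is
    one predict + update step.  Output quaternions are sign-continuous.
    """
    params = params or KFParams()
    if len(imu1) != len(imu2):
        raise InvalidInputError("recordings must have equal length")
    n = len(imu1)
    dt = imu1.dt
    state = initialize(imu1, imu2, params)
    H = _observation_matrix(params.g)

    q_out = np.empty((n, 4))
    g1_out = np.empty((n, 3))
    g2_out = np.empty((n, 3))
    at1_out = np.empty((n, 3))
    at2_out = np.empty((n, 3))
    P_out = np.empty((n, 10, 10)) if return_covariance else None

    # the true-acceleration recursion starts from a zeroed history
    q_out[0] = state.q21
    g1_out[0] = state.g1
    g2_out[0] = state.g2
    at1_out[0] = state.a_tilde1
    at2_out[0] = state.a_tilde2
    if return_covariance:
        P_out[0] = state.P

    for k in range(1, n):
        state = time_update(state, imu1.gyro[k - 1], imu2.gyro[k - 1], dt, params)

        zg1, _ = gravity_measurement(imu1.accel[k], state.a_tilde1, params.c, params.g)
        zg2, _ = gravity_measurement(imu2.accel[k], state.a_tilde2, params.c, params.g)
        zq = quaternion_measurement(state.g1, state.g2, imu1.mag[k], imu2.mag[k])
        if np.dot(zq, state.q21) < 0.0:   # resolve the q/-q ambiguity
            zq = -zq
        zeta = np.concatenate([zg1, zg2, zq])

        M = measurement_noise(state.hist1, state.hist2, params)
        S = H @ state.P @ H.T + M
        try:
            K = np.linalg.solve(S.T, (state.P @ H.T).T).T
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"innovation covariance singular: {exc}",
                                 sample_index=k) from exc
        chi = state.chi + K @ (zeta - H @ state.chi)
        P = (np.eye(10) - K @ H) @ state.P
        P = 0.5 * (P + P.T)
        if not np.all(np.isfinite(P)):
            raise NumericalError("covariance update diverged", sample_index=k)

        state.g1 = chi[0:3] / np.linalg.norm(chi[0:3])
        state.g2 = chi[3:6] / np.linalg.norm(chi[3:6])
        q = quat_normalize(chi[6:10])
        if np.dot(q, q_out[k - 1]) < 0.0:
            q = -q
        state.q21 = q
        state.P = P

        state.a_tilde1 = imu1.accel[k] - params.g * state.g1
        state.a_tilde2 = imu2.accel[k] - params.g * state.g2
        state.hist1.append(state.a_tilde1.copy())
        state.hist2.append(state.a_tilde2.copy())

        q_out[k] = state.q21
        g1_out[k] = state.g1
        g2_out[k] = state.g2
        at1_out[k] = state.a_tilde1
        at2_out[k] = state.a_tilde2
        if return_covariance:
            P_out[k] = P

    return SsroResult(t=imu1.t.copy(), q21=q_out, g1=g1_out, g2=g2_out,
                      a_tilde1=at1_out, a_tilde2=at2_out, P=P_out)
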