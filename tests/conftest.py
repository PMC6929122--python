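import numpy as np
import pytest

from hipkin.preprocess import ImuRecording
from hipkin.rotations import quat_from_axis_angle
from hipkin.synthdata import ChainGeometry, Sinusoid, SumProfile

D2R = np.pi / 180.0


def quat_error_deg(q_est, q_true):
    """Axis-angle magnitude of the relative rotation between two quaternion
    traces, in degrees (sign-insensitive)."""
    d = np.abs(np.sum(np.atleast_2d(q_est) * np.atleast_2d(q_true), axis=-1))
    return 2.0 * np.degrees(np.arccos(np.clip(d, -1.0, 1.0)))


def vector_angle_deg(u, v):
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    return np.degrees(np.arccos(np.clip(abs(np.dot(u, v)), -1.0, 1.0)))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def static_recording():
    """1 s of a perfectly still sensor with gravity along +z."""
    n = 128
    t = np.arange(n) / 128.0
    return ImuRecording(
        t=t, gyro=np.zeros((n, 3)),
        accel=np.tile([0.0, 0.0, 9.81], (n, 1)),
        mag=np.tile([0.5, 0.0, -0.866], (n, 1)), fs=128.0)


@pytest.fixture
def hip_geometry():
    """Pelvis-above / thigh-below sensor placement, rotated mountings."""
    return ChainGeometry(
        r1=np.array([0.05, 0.25, 0.02]),
        r2=np.array([-0.03, -0.20, 0.01]),
        mount1=quat_from_axis_angle([0.3, 1.0, 0.2], 0.8),
        mount2=quat_from_axis_angle([1.0, -0.5, 0.4], -1.1))


@pytest.fixture
def walking_profiles():
    """FE-dominant 1 Hz walking-like hip angle profiles (degrees)."""
    return (Sinusoid(30.0, 1.0), Sinusoid(8.0, 1.0, np.pi / 2),
            Sinusoid(8.0, 1.0, np.pi))


@pytest.fixture
def pelvis_sway():
    """Small pelvis orientation sway (radians) for walking-like trials."""
    return (Sinusoid(3 * D2R, 1.0, 0.3), Sinusoid(2 * D2R, 2.0, 0.9),
            Sinusoid(3 * D2R, 1.0, 1.7))


@pytest.fixture
def calibration_profiles():
    """Star-like calibration: slow sweeps plus fast low-amplitude oscillation."""
    profs = (SumProfile((Sinusoid(35, 0.2), Sinusoid(10, 1.4, 0.4))),
             SumProfile((Sinusoid(20, 0.15, 1.0), Sinusoid(8, 1.7, 1.2))),
             SumProfile((Sinusoid(15, 0.25, 2.0), Sinusoid(8, 1.2, 2.2))))
    base = (SumProfile((Sinusoid(8 * D2R, 0.3), Sinusoid(4 * D2R, 1.3, 0.5))),
            SumProfile((Sinusoid(6 * D2R, 0.23, 0.8), Sinusoid(4 * D2R, 1.6, 1.1))),
            SumProfile((Sinusoid(6 * D2R, 0.13, 1.5), Sinusoid(4 * D2R, 1.1, 1.9))))
    return profs, base
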