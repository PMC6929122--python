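"""Signal conditioning for raw MIMU channels.

Angular velocity, acceleration, and magnetometer channels are low-pass
zero-phase filtered (4th-order Butterworth, forward-backward) with a 15 Hz
cutoff before any estimation step.  Angular acceleration is obtained from
angular velocity by second-order central differences and then zero-phase
filtered at 12 Hz.  Angle traces can be resampled (linear interpolation)
onto a lower reference rate for comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .exceptions import InsufficientDataError, InvalidInputError, InvalidParameterError

__all__ = [
    "ImuRecording",
    "lowpass_zero_phase",
    "angular_acceleration",
    "resample",
    "preprocess_recording",
]

DEFAULT_CHANNEL_CUTOFF_HZ = 15.0
DEFAULT_ANGACC_CUTOFF_HZ = 12.0
FILTER_ORDER = 4


@dataclass
class ImuRecording:
    """Synchronized gyro/accelerometer/magnetometer time series.

    Attributes
    ----------
    t : (N,) float array, seconds, uniformly spaced at 1/fs
    gyro : (N, 3) angular velocity, rad/s, sensor frame
    accel : (N, 3) specific force, m/s^2, sensor frame
    mag : (N, 3) magnetic field, arbitrary consistent units, sensor frame
    fs : sampling rate, Hz
    """

    t: np.ndarray
    gyro: np.ndarray
    accel: np.ndarray
    mag: np.ndarray
    fs: float

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.mag = np.asarray(self.mag, dtype=float)
        n = len(self.t)
        if n < 2:
            raise InsufficientDataError("recording must contain at least 2 samples")
        for name in ("gyro", "accel", "mag"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise InvalidInputError(
                    f"{name} shape {arr.shape} does not match ({n}, 3)")
        dt = np.diff(self.t)
        if np.max(np.abs(dt - 1.0 / self.fs)) > 1e-6:
            raise InvalidInputError("time stamps are not uniform at 1/fs")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return 1.0 / self.fs


def lowpass_zero_phase(x, fc: float, fs: float, order: int = FILTER_ORDER) -> np.ndarray:
    """Zero-phase low-pass filter (Butterworth, applied forward-backward).

    The effective magnitude response is the squared Butterworth response;
    phase lag is identically zero and DC gain is 1.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("signal contains non-finite values")
    if fc <= 0 or fc >= fs / 2.0:
        raise InvalidParameterError(
            f"cutoff {fc} Hz must lie in (0, Nyquist={fs / 2.0} Hz)")
    sos = signal.butter(order, fc, btype="low", fs=fs, output="sos")
    padlen = 3 * (2 * order + 1)
    if x.shape[0] <= padlen:
        raise InsufficientDataError(
            f"need more than {padlen} samples for zero-phase filtering, got {x.shape[0]}")
    return signal.sosfiltfilt(sos, x, axis=0)


def angular_acceleration(gyro, dt: float, fc: float | None = DEFAULT_ANGACC_CUTOFF_HZ
                         ) -> np.ndarray:
    """Angular acceleration from angular velocity by central differences.

    Interior samples use the second-order form ``(w[k+1] - w[k-1]) / (2 dt)``;
    the endpoints fall back to first-order one-sided differences so the
    output has the same length as the input.  When ``fc`` is given the
    result is zero-phase low-pass filtered at that cutoff (default 12 Hz).
    """
    gyro = np.asarray(gyro, dtype=float)
    if gyro.shape[0] < 3:
        raise InsufficientDataError("need at least 3 samples for differentiation")
    out = np.empty_like(gyro)
    out[1:-1] = (gyro[2:] - gyro[:-2]) / (2.0 * dt)
    out[0] = (gyro[1] - gyro[0]) / dt
    out[-1] = (gyro[-1] - gyro[-2]) / dt
    if fc is not None:
        out = lowpass_zero_phase(out, fc, 1.0 / dt)
    return out


def resample(t, x, fs_out: float):
    """Linearly interpolate ``x(t)`` onto a uniform grid at ``fs_out`` Hz.

    Returns ``(t_new, x_new)`` spanning the same interval, starting at
    ``t[0]``.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if fs_out <= 0:
        raise InvalidParameterError("output rate must be positive")
    n_out = int(np.floor((t[-1] - t[0]) * fs_out)) + 1
    t_new = t[0] + np.arange(n_out) / fs_out
    if x.ndim == 1:
        x_new = np.interp(t_new, t, x)
    else:
        x_new = np.column_stack([np.interp(t_new, t, col) for col in x.T])
    return t_new, x_new


def preprocess_recording(rec: ImuRecording,
                         fc: float = DEFAULT_CHANNEL_CUTOFF_HZ) -> ImuRecording:
    """Return a copy of ``rec`` with all three channels zero-phase filtered."""
    return replace(
        rec,
        gyro=lowpass_zero_phase(rec.gyro, fc, rec.fs),
        accel=lowpass_zero_phase(rec.accel, fc, rec.fs),
        mag=lowpass_zero_phase(rec.mag, fc, rec.fs),
    )
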