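"""Agreement statistics between an estimated and a reference angle trace.

Angle differences are wrapped to the minimal circular distance before any
statistic is computed (a raw difference of 350 deg is really -10 deg).
Statistics: RMSE of the wrapped differences; OLS slope/intercept of the
estimate on the reference (slope tracks changes, intercept measures
bias); range of motion with a start-up exclusion rule; and drift, the
slope of the wrapped error against time, with a Wilcoxon signed-rank
helper for testing a sample of per-subject drift slopes against zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError, InvalidInputError

__all__ = [
    "AgreementStats",
    "wrap_difference",
    "rmse",
    "regression",
    "classify_slope",
    "range_of_motion",
    "drift",
    "wilcoxon_drift",
    "agreement",
]

ROM_EXCLUSION_THRESHOLD_S = 30.0
ROM_EXCLUSION_S = 10.0


@dataclass
class AgreementStats:
    rmse: float       # degrees
    slope: float
    intercept: float  # degrees
    r: float
    romd: float       # degrees, estimate ROM - reference ROM
    drift: float      # degrees / s
    drift_p: float
    n: int


def wrap_difference(est, ref):
    """Wrapped angle difference est - ref in (-180, 180] degrees."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if not (np.all(np.isfinite(est)) and np.all(np.isfinite(ref))):
        raise InvalidInputError("angles must be finite")
    d = (est - ref) % 360.0
    return np.where(d > 180.0, d - 360.0, d)


def rmse(est, ref) -> float:
    """Root mean square of the wrapped angle differences, degrees."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise InvalidInputError("traces must have equal length")
    if est.size < 1:
        raise InvalidInputError("traces must be non-empty")
    d = wrap_difference(est, ref)
    return float(np.sqrt(np.mean(d ** 2)))


def regression(est, ref):
    """OLS of the estimate on the reference: returns (slope, intercept, r)."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape or est.size < 3:
        raise InvalidInputError("need two equal-length traces with n >= 3")
    if np.ptp(ref) == 0.0:
        raise InvalidInputError("reference trace is constant; regression undefined")
    res = stats.linregress(ref, est)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def classify_slope(slope: float) -> str:
    """Qualitative tracking grade from the regression slope."""
    d = abs(slope - 1.0)
    if d <= 0.1:
        return "excellent"
    if d <= 0.3:
        return "good"
    if d <= 0.5:
        return "moderate"
    return "poor"


def range_of_motion(trace, t) -> float:
    """max - min of the trace, excluding the first 10 s of trials > 30 s."""
    trace = np.asarray(trace, dtype=float)
    t = np.asarray(t, dtype=float)
    if trace.size == 0:
        raise InsufficientDataError("empty trace")
    duration = t[-1] - t[0]
    if duration > ROM_EXCLUSION_THRESHOLD_S:
        keep = t >= t[0] + ROM_EXCLUSION_S
        trace = trace[keep]
        if trace.size == 0:
            raise InsufficientDataError("no samples left after start-up exclusion")
    return float(np.max(trace) - np.min(trace))


def drift(est, ref, t):
    """Slope (deg/s) and p-value of the wrapped error regressed on time."""
    t = np.asarray(t, dtype=float)
    d = wrap_difference(est, ref)
    if d.size < 3:
        raise InvalidInputError("need n >= 3 for drift regression")
    res = stats.linregress(t, d)
    return float(res.slope), float(res.pvalue)


def wilcoxon_drift(slopes, exact_n: int = 25):
    """Two-sided Wilcoxon signed-rank test of drift slopes against zero."""
    slopes = np.asarray(slopes, dtype=float)
    method = "exact" if slopes.size <= exact_n else "auto"
    res = stats.wilcoxon(slopes, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def agreement(est, ref, t) -> AgreementStats:
    """All agreement statistics for one angle trace pair."""
    slope, intercept, r = regression(est, ref)
    d_slope, d_p = drift(est, ref, t)
    return AgreementStats(
        rmse=rmse(est, ref),
        slope=slope,
        intercept=intercept,
        r=r,
        romd=range_of_motion(est, t) - range_of_motion(ref, t),
        drift=d_slope,
        drift_p=d_p,
        n=int(np.asarray(est).size),
    )
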