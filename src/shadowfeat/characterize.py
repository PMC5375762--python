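"""Calibration: series characterization, smoother choice, base windows.

A short initial span of each feature is inspected once, before any
shadow values are produced. Three questions are asked of the span — is
it stationary, does it trend, is it a bare random walk — and their
answers route to a smoother through a small rule table. The same span
yields the starting Hurst exponent, the power-law intercept log C and,
via the continuity grade, the base sliding-window length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.tsa.stattools import adfuller

from shadowfeat.hurst import (
    DEFAULT_GRADE_MAPPING,
    DEFAULT_W_MAX,
    DEFAULT_W_MIN,
    InsufficientDataError,
    continuity_grade,
    fit_hurst_start,
    window_length_for_grade,
)
from shadowfeat.timeseries_io import SensorSeries

SMOOTHERS = (
    "moving_average",
    "weighted_moving_average",
    "naive_last_value",
    "detrend_then_moving_average",
)

_MIN_TEST_LEN = 32
# Mann-Kendall cost is quadratic in span length; cap the pairs scanned.
_MK_MAX_N = 2000


@dataclass
class FeatureCalibration:
    """Calibration outputs for one feature."""

    feature: str
    H_start: float
    log_intercept: float
    smoother: str
    base_window: int
    stationary: bool
    trend: bool
    random_walk: bool
    grade: int
    intensity: str
    # detrend_then_moving_average operates on residuals from this line
    # (fitted on the calibration span, extrapolated forward).
    trend_slope: float = 0.0
    trend_intercept: float = 0.0


@dataclass
class CalibrationResult:
    """Per-feature calibration plus the span it was computed on."""

    features: dict[str, FeatureCalibration]
    calibration_span: int

    def __getitem__(self, feature: str) -> FeatureCalibration:
        return self.features[feature]

    def to_dict(self) -> dict:
        return {
            "calibration_span": self.calibration_span,
            "features": {
                name: {
                    "H_start": fc.H_start,
                    "log_intercept": fc.log_intercept,
                    "smoother": fc.smoother,
                    "base_window": fc.base_window,
                    "stationary": fc.stationary,
                    "trend": fc.trend,
                    "random_walk": fc.random_walk,
                    "grade": fc.grade,
                    "intensity": fc.intensity,
                    "trend_slope": fc.trend_slope,
                    "trend_intercept": fc.trend_intercept,
                }
                for name, fc in self.features.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CalibrationResult":
        feats = {
            name: FeatureCalibration(feature=name, **vals)
            for name, vals in d["features"].items()
        }
        return cls(features=feats, calibration_span=int(d["calibration_span"]))


def test_stationarity(segment: Sequence[float], alpha: float = 0.05) -> bool:
    """True if an augmented Dickey-Fuller test rejects a unit root.

    A constant (zero-variance) segment is treated as stationary.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.size < _MIN_TEST_LEN:
        raise InsufficientDataError(f"need >= {_MIN_TEST_LEN} samples")
    if np.ptp(seg) == 0.0:
        return True
    _, pvalue, *_ = adfuller(seg, autolag="AIC")
    return bool(pvalue < alpha)


def _mann_kendall(seg: np.ndarray) -> tuple[float, float]:
    """Mann-Kendall S statistic and two-sided p-value (tie-corrected)."""
    n = seg.size
    s = 0
    for k in range(n - 1):
        s += np.sign(seg[k + 1:] - seg[k]).sum()
    # tie correction for the variance of S
    _, counts = np.unique(seg, return_counts=True)
    tie_term = (counts * (counts - 1) * (2 * counts + 5)).sum()
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    if var_s <= 0:
        return float(s), 1.0
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return float(s), float(p)


def test_trend(segment: Sequence[float], alpha: float = 0.05) -> bool:
    """True if a Mann-Kendall test finds a monotone trend (two-sided)."""
    seg = np.asarray(segment, dtype=float)
    if seg.size < _MIN_TEST_LEN:
        raise InsufficientDataError(f"need >= {_MIN_TEST_LEN} samples")
    if seg.size > _MK_MAX_N:
        idx = np.linspace(0, seg.size - 1, _MK_MAX_N).astype(int)
        seg = seg[idx]
    _, p = _mann_kendall(seg)
    return bool(p < alpha)


def test_random_walk(segment: Sequence[float], alpha: float = 0.05) -> bool:
    """True for a bare random walk: non-stationary with unforecastable steps.

    Operationally: the segment fails the stationarity test AND its first
    differences show no significant lag-1 autocorrelation (so the steps
    carry no linear structure to exploit).
    """
    seg = np.asarray(segment, dtype=float)
    if seg.size < _MIN_TEST_LEN:
        raise InsufficientDataError(f"need >= {_MIN_TEST_LEN} samples")
    if test_stationarity(seg, alpha=alpha):
        return False
    d = np.diff(seg)
    d = d - d.mean()
    denom = (d * d).sum()
    if denom == 0.0:
        return True  # constant steps: nothing to forecast beyond the level
    r1 = (d[:-1] * d[1:]).sum() / denom
    crit = stats.norm.ppf(1 - alpha / 2) / np.sqrt(d.size)
    return bool(abs(r1) <= crit)


def choose_smoother(
    stationary: bool, trend: bool, random_walk: bool,
    weighting: str = "uniform",
) -> str:
    """Route the three characterization flags to a smoother.

    Rule table: a trend wins (detrend first, then average); else a bare
    random walk gets the naive last-value fit (its best predictor); else
    the moving average — the branch quasi-periodic activity data takes,
    being stationary with no overall trend. ``weighting="linear"``
    upgrades the moving-average branch to its linearly weighted form.
    """
    if trend:
        return "detrend_then_moving_average"
    if random_walk:
        return "naive_last_value"
    ma = "weighted_moving_average" if weighting == "linear" else "moving_average"
    return ma


def default_calibration_span(n: int) -> int:
    """min(1000, ceil(0.1 n)), floored at 64 samples."""
    return max(64, min(1000, int(np.ceil(0.1 * n))))


def calibrate(
    series: SensorSeries,
    calibration_span: int | None = None,
    alpha: float = 0.05,
    grade_mapping: Mapping[int, int] | None = None,
    w_min: int = DEFAULT_W_MIN,
    w_max: int = DEFAULT_W_MAX,
    weighting: str = "uniform",
) -> CalibrationResult:
    """Characterize every feature on the initial span of a series.

    For each feature: run the stationarity/trend/random-walk tests,
    choose a smoother, fit H_start and log C by R/S regression, and map
    the continuity grade of H_start to the base window length.
    Deterministic given (series, parameters): the tests are closed-form.
    """
    n = series.n_samples
    span = default_calibration_span(n) if calibration_span is None else int(calibration_span)
    if span < 64:
        raise InsufficientDataError(f"calibration span {span} < 64")
    if span > n:
        raise InsufficientDataError(
            f"calibration span {span} exceeds series length {n}"
        )
    mapping = dict(DEFAULT_GRADE_MAPPING if grade_mapping is None else grade_mapping)

    feats: dict[str, FeatureCalibration] = {}
    idx = np.arange(span, dtype=float)
    for j, name in enumerate(series.feature_names):
        seg = series.values[:span, j]
        stationary = test_stationarity(seg, alpha=alpha)
        trend = test_trend(seg, alpha=alpha)
        random_walk = test_random_walk(seg, alpha=alpha)
        smoother = choose_smoother(stationary, trend, random_walk, weighting)

        if np.ptp(seg) == 0.0:
            # Flat span: no power law to fit; neutral memory, no trend.
            H, logc = 0.5, 0.0
        else:
            est = fit_hurst_start(seg)
            H, logc = est.H, est.log_intercept
        grade, intensity = continuity_grade(H)
        base_w = window_length_for_grade(grade, mapping, w_min, w_max)

        slope, intercept = 0.0, float(seg.mean())
        if smoother == "detrend_then_moving_average" and np.ptp(seg) > 0:
            slope, intercept = np.polyfit(idx, seg, 1)

        feats[name] = FeatureCalibration(
            feature=name, H_start=float(H), log_intercept=float(logc),
            smoother=smoother, base_window=int(base_w),
            stationary=stationary, trend=trend, random_walk=random_walk,
            grade=grade, intensity=intensity,
            trend_slope=float(slope), trend_intercept=float(intercept),
        )
    return CalibrationResult(features=feats, calibration_span=span)
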