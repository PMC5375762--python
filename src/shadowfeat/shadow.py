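"""Shadow-feature generation: adaptive trailing smoothers, batch + streaming.

A shadow value at position i is a trailing smoother over the last w_i
raw values ending at i, with the current sample boosted by (phi_i + 1),
where phi_i = (|H_i| - 0.5) / 0.5 rescales the window's dynamic Hurst
exponent into [-1, 1]. Persistent windows (H > 0.5) therefore lean the
shadow toward the newest sample; anti-persistent windows damp it. The
window length itself follows the continuity grade of H_dynamic, so the
smoother stretches over stretches of strong long-range memory and
tightens where the signal is choppy.

The streaming kernel is the single source of truth: batch generation
replays it, so batch and stream outputs are bit-identical by
construction, and an emitted value only ever depends on already-seen
data (window-length changes take effect on the step after the H update).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from shadowfeat.characterize import CalibrationResult, FeatureCalibration
from shadowfeat.hurst import (
    DEFAULT_GRADE_MAPPING,
    DEFAULT_W_MAX,
    DEFAULT_W_MIN,
    MIN_RS_WINDOW,
    continuity_grade,
    hurst_dynamic,
    window_length_for_grade,
)
from shadowfeat.timeseries_io import SHADOW_SUFFIX, SensorSeries, ShadowSeries


@dataclass
class ShadowConfig:
    """Knobs of the shadow generator.

    weighting: "uniform" (plain trailing mean) or "linear" (weights
    w..1, newest heaviest). dynamic_window: re-estimate H in-window each
    step and adapt the window length; off = keep the calibration base
    window. phi_enabled: apply the (phi+1) boost to the current sample;
    off = phi fixed at 0. normalize_phi: also add phi to the weight-sum
    denominator so the smoother stays a weighted mean (off by default:
    the canonical formulas inflate only the numerator).
    unknown_policy: how augmentation treats warm-up slots.
    """

    weighting: str = "uniform"
    dynamic_window: bool = True
    phi_enabled: bool = True
    grade_mapping: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_GRADE_MAPPING))
    w_min: int = DEFAULT_W_MIN
    w_max: int = DEFAULT_W_MAX
    normalize_phi: bool = False
    unknown_policy: str = "mark"
    calibration_span: int | None = None

    def __post_init__(self) -> None:
        if self.weighting not in ("uniform", "linear"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.unknown_policy not in ("mark", "drop", "backfill"):
            raise ValueError(f"unknown policy {self.unknown_policy!r}")
        if self.w_min < 2:
            raise ValueError("w_min must be >= 2")
        if self.w_max < self.w_min:
            raise ValueError("w_max must be >= w_min")


def phi_from_hurst(H: float) -> float:
    """phi = (|H| - 0.5) / 0.5, mapping H in (0, 1] onto [-1, 1]."""
    if not (0.0 < H <= 1.0):
        raise ValueError(f"H must be in (0, 1], got {H}")
    return (abs(H) - 0.5) / 0.5


def shadow_uniform(window: Sequence[float], phi: float = 0.0,
                   normalize_phi: bool = False) -> float:
    """Uniform trailing smoother with a phi-boosted current sample.

    ``window`` is ordered oldest -> newest; the newest element is the
    current sample r_i. Returns ((phi+1) r_i + r_{i-1} + ... ) / w. The
    denominator stays w even when phi != 0 (canonical form) unless
    ``normalize_phi``.
    """
    w = len(window)
    if w < 2:
        raise ValueError("window must hold at least 2 values")
    num = (phi + 1.0) * window[-1] + float(np.sum(np.asarray(window[:-1], dtype=float)))
    den = w + phi if normalize_phi else w
    return float(num / den)


def shadow_weighted(window: Sequence[float], phi: float = 0.0,
                    normalize_phi: bool = False) -> float:
    """Linearly weighted trailing smoother (newest weight w, oldest 1).

    Returns ((phi+1) w r_i + (w-1) r_{i-1} + ... + 1 r_{i-w+1}) over the
    triangular weight sum w(w+1)/2.
    """
    w = len(window)
    if w < 2:
        raise ValueError("window must hold at least 2 values")
    arr = np.asarray(window, dtype=float)
    weights = np.arange(1, w + 1, dtype=float)
    num = (phi + 1.0) * w * arr[-1] + float(np.dot(weights[:-1], arr[:-1]))
    den = w * (w + 1) / 2.0
    if normalize_phi:
        den += phi * w
    return float(num / den)


class _FeatureKernel:
    """One-pass shadow generator for a single feature.

    Constant memory: holds at most w_max recent values. The emitted
    value at step i is a pure function of values seen up to i; the
    window-length consequence of the step-i Hurst update only applies
    from step i+1.
    """

    def __init__(self, calib: FeatureCalibration, config: ShadowConfig):
        self.calib = calib
        self.config = config
        self.base_window = int(np.clip(calib.base_window, config.w_min,
                                       config.w_max))
        self.target_w = self.base_window
        self.buffer: list[float] = []
        self.H = 0.5  # fallback until a window supports an estimate
        self.position = -1
        self.closed = False

    def _smooth(self, phi: float) -> float:
        cfg = self.config
        calib = self.calib
        buf = self.buffer
        smoother = calib.smoother
        if smoother == "naive_last_value":
            return buf[-2]
        if smoother == "detrend_then_moving_average":
            i = self.position
            idx = np.arange(i - len(buf) + 1, i + 1, dtype=float)
            trend = calib.trend_slope * idx + calib.trend_intercept
            resid = np.asarray(buf, dtype=float) - trend
            sm = (shadow_weighted if cfg.weighting == "linear"
                  else shadow_uniform)(resid, phi, cfg.normalize_phi)
            return sm + float(trend[-1])
        if cfg.weighting == "linear" or smoother == "weighted_moving_average":
            return shadow_weighted(buf, phi, cfg.normalize_phi)
        return shadow_uniform(buf, phi, cfg.normalize_phi)

    def push(self, value: float) -> float | None:
        """Consume one sample; return the shadow value or None (warm-up)."""
        if self.closed:
            raise RuntimeError("push after stream closed")
        self.position += 1
        self.buffer.append(float(value))
        if len(self.buffer) > self.target_w:
            del self.buffer[: len(self.buffer) - self.target_w]

        warm_up = self.position < self.base_window - 1
        cfg = self.config

        if cfg.dynamic_window and len(self.buffer) >= MIN_RS_WINDOW:
            self.H = hurst_dynamic(self.buffer, self.calib.log_intercept,
                                   previous=self.H)
        h_for_phi = self.H if cfg.dynamic_window else self.calib.H_start

        out: float | None = None
        if not warm_up:
            phi = phi_from_hurst(h_for_phi) if cfg.phi_enabled else 0.0
            out = self._smooth(phi)

        if cfg.dynamic_window and len(self.buffer) >= MIN_RS_WINDOW:
            # takes effect next step; shrink drops oldest samples then
            grade, _ = continuity_grade(self.H)
            self.target_w = window_length_for_grade(
                grade, cfg.grade_mapping, cfg.w_min, cfg.w_max)
        return out

    def close(self) -> None:
        self.closed = True


class ShadowStream:
    """Streaming shadow generator over all features of a calibration.

    Per-feature state is independent, so pushes may interleave across
    features in any order. ``push(feature, value)`` returns the shadow
    value or None during the feature's warm-up; ``push_row`` consumes
    one value per feature. Outputs are slot-for-slot identical to
    :func:`generate_shadow_batch`.
    """

    def __init__(self, calibration: CalibrationResult,
                 config: ShadowConfig | None = None):
        self.config = config or ShadowConfig()
        self.kernels = {
            name: _FeatureKernel(fc, self.config)
            for name, fc in calibration.features.items()
        }

    def push(self, feature: str, value: float) -> float | None:
        return self.kernels[feature].push(value)

    def push_row(self, row: Mapping[str, float] | Sequence[float]
                 ) -> dict[str, float | None]:
        if not isinstance(row, Mapping):
            row = dict(zip(self.kernels, row))
        return {name: self.kernels[name].push(row[name]) for name in self.kernels}

    def window_length(self, feature: str) -> int:
        """Current effective window length (buffer fill) of a feature."""
        return len(self.kernels[feature].buffer)

    def close(self) -> None:
        for k in self.kernels.values():
            k.close()


def generate_shadow_batch(
    series: SensorSeries,
    calibration: CalibrationResult,
    config: ShadowConfig | None = None,
    track_windows: bool = False,
) -> ShadowSeries | tuple[ShadowSeries, np.ndarray]:
    """Generate the full shadow matrix for a series.

    Replays the streaming kernel per feature, so results match
    :class:`ShadowStream` exactly. Warm-up slots (the first
    base_window - 1 rows of each column) are NaN with the unknown mask
    set. With ``track_windows`` also returns the N x M matrix of
    effective window lengths used at each emission (0 during warm-up).
    """
    config = config or ShadowConfig()
    missing = [f for f in series.feature_names if f not in calibration.features]
    if missing:
        raise KeyError(f"calibration missing features {missing}")
    n, m = series.values.shape
    out = np.full((n, m), np.nan)
    mask = np.zeros((n, m), dtype=bool)
    windows = np.zeros((n, m), dtype=int)
    for j, name in enumerate(series.feature_names):
        kernel = _FeatureKernel(calibration.features[name], config)
        col = series.values[:, j]
        for i in range(n):
            val = kernel.push(col[i])
            if val is None:
                mask[i, j] = True
            else:
                out[i, j] = val
                windows[i, j] = len(kernel.buffer)
    shadow = ShadowSeries(
        values=out, unknown_mask=mask,
        feature_names=[f + SHADOW_SUFFIX for f in series.feature_names],
    )
    return (shadow, windows) if track_windows else shadow
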