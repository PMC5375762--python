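"""Rescaled-range (R/S) statistics and Hurst-exponent machinery.

The Hurst exponent H indexes the long-range memory of a series: H near
0.5 means memoryless increments, H -> 1 persistent (trending) motion,
H < 0.5 anti-persistent (mean-reverting) motion. Here H drives two
things: a calibration-time estimate ``H_start`` fitted as the slope of
log(R/S) against log(block length), and a per-window ``H_dynamic``
obtained by inverting that same power law inside a sliding window using
the calibrated intercept log C. The continuity-intensity grade of H
(a +/-1..+/-5 band) then selects the smoothing-window length: the
stronger the long-range memory, the longer the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

#: Default grade-magnitude -> window-length mapping (samples). The method
#: only mandates monotonicity: stronger memory, longer window.
DEFAULT_GRADE_MAPPING: dict[int, int] = {1: 8, 2: 16, 3: 32, 4: 64, 5: 128}

DEFAULT_W_MIN = 2
DEFAULT_W_MAX = 512

#: Minimum window length for which an R/S value is meaningful.
MIN_RS_WINDOW = 4

_H_FLOOR = 1e-6  # clamp target for non-positive fitted slopes

# Continuity-intensity bands: (lower-exclusive, upper-inclusive, grade).
# Positive grades cover persistent H > 0.5, negative grades the
# anti-persistent mirror; magnitude 1..5 orders intensity.
_GRADE_BANDS: list[tuple[float, float, int]] = [
    (0.80, 1.00, 5),
    (0.75, 0.80, 4),
    (0.65, 0.75, 3),
    (0.55, 0.65, 2),
    (0.50, 0.55, 1),
    (0.45, 0.50, -1),
    (0.35, 0.45, -2),
    (0.25, 0.35, -3),
    (0.20, 0.25, -4),
    (0.00, 0.20, -5),
]

_INTENSITY_LABELS = {1: "Very weak", 2: "Weak", 3: "Normal strong",
                     4: "Strong", 5: "Very strong"}


class DegenerateSegmentError(ValueError):
    """Segment has zero variance; R/S is undefined (caller picks fallback)."""


class InsufficientDataError(ValueError):
    """Too few samples (or usable scales) for a Hurst fit."""


@dataclass
class HurstEstimate:
    """A fitted Hurst exponent with its regression diagnostics.

    ``H`` is the OLS slope of log(mean R/S) on log(scale), clamped to
    (0, 1]; ``log_intercept`` is the fitted log C reused when inverting
    the power law for dynamic (in-window) estimates.
    """

    H: float
    log_intercept: float
    scales: list[int]
    rs_values: list[float]
    n_points: int


def cumulative_deviates(segment: Sequence[float]) -> np.ndarray:
    """Running sum of mean-deviations: delta_t = sum_{i<=t} (r_i - mu).

    The final element telescopes to zero up to rounding.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.size == 0:
        raise InsufficientDataError("empty segment")
    return np.cumsum(seg - seg.mean())


def rescaled_range(segment: Sequence[float]) -> float:
    """R/S of a segment: range of cumulative deviates over population SD.

    Translation- and positive-scale-invariant. Raises
    :class:`DegenerateSegmentError` on zero variance.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.size < 2:
        raise InsufficientDataError("R/S needs at least 2 points")
    sd = seg.std()  # population (1/n) standard deviation
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateSegmentError("zero-variance segment")
    delta = np.cumsum(seg - seg.mean())
    return float((delta.max() - delta.min()) / sd)


def default_scales(n: int) -> list[int]:
    """Powers of two from 8 (falling back to 4) up to n // 4."""
    for lo in (8, 4):
        scales = []
        s = lo
        while s <= n // 4:
            scales.append(s)
            s *= 2
        if len(scales) >= 3:
            return scales
    return scales


def fit_hurst_start(
    series: Sequence[float],
    scales: Sequence[int] | None = None,
) -> HurstEstimate:
    """Estimate H by power-law regression of block-averaged R/S on scale.

    For each scale the series is partitioned into non-overlapping blocks
    of that length; the mean R/S over blocks realizes the expectation in
    the power law E[R/S] = C * n^H. OLS of log(mean R/S) on log(scale)
    yields slope H (clamped to (0, 1]) and intercept log C.
    """
    y = np.asarray(series, dtype=float)
    n = y.size
    if n < 32:
        raise InsufficientDataError(f"need >= 32 samples, got {n}")
    if scales is None:
        scales = default_scales(n)
    scales = sorted(int(s) for s in scales)
    if any(s < MIN_RS_WINDOW for s in scales):
        raise ValueError(f"scales must be >= {MIN_RS_WINDOW}")

    used_scales: list[int] = []
    mean_rs: list[float] = []
    for s in scales:
        blocks = n // s
        if blocks < 1:
            continue
        vals = []
        for b in range(blocks):
            try:
                vals.append(rescaled_range(y[b * s:(b + 1) * s]))
            except DegenerateSegmentError:
                continue
        if vals:
            used_scales.append(s)
            mean_rs.append(float(np.mean(vals)))

    if len(used_scales) < 3:
        raise InsufficientDataError(
            f"only {len(used_scales)} usable scales (need >= 3)"
        )

    log_s = np.log(used_scales)
    log_rs = np.log(mean_rs)
    slope, intercept = np.polyfit(log_s, log_rs, 1)
    H = float(np.clip(slope, _H_FLOOR, 1.0))
    return HurstEstimate(H=H, log_intercept=float(intercept),
                         scales=used_scales, rs_values=mean_rs, n_points=n)


def hurst_dynamic(
    window: Sequence[float],
    log_intercept: float,
    previous: float | None = None,
) -> float:
    """In-window Hurst estimate by inverting the calibrated power law.

    H = (log(R/S of window) - log C) / log(|w|), clamped to (0, 1]. A
    degenerate (zero-variance) window returns ``previous`` (or 0.5 when
    no previous estimate exists) instead of raising, so constant
    stretches of a stream degrade to a plain moving average.
    """
    w = np.asarray(window, dtype=float)
    if w.size < MIN_RS_WINDOW:
        raise InsufficientDataError(
            f"dynamic H needs >= {MIN_RS_WINDOW} points, got {w.size}"
        )
    try:
        rs = rescaled_range(w)
    except DegenerateSegmentError:
        return 0.5 if previous is None else previous
    H = (np.log(rs) - log_intercept) / np.log(w.size)
    return float(np.clip(H, _H_FLOOR, 1.0))


def continuity_grade(H: float) -> tuple[int, str]:
    """Continuity-intensity grade of a Hurst exponent.

    Maps H in (0, 1] to (grade, intensity-label), grade in +/-1..+/-5,
    using lower-exclusive / upper-inclusive bands; e.g. H = 0.9 is
    (5, "Very strong") and the H = 0.5 boundary belongs to grade -1.
    """
    if not (0.0 < H <= 1.0):
        raise ValueError(f"H must be in (0, 1], got {H}")
    for lo, hi, grade in _GRADE_BANDS:
        if lo < H <= hi:
            return grade, _INTENSITY_LABELS[abs(grade)]
    raise AssertionError("unreachable: bands partition (0, 1]")


def window_length_for_grade(
    grade: int,
    mapping: Mapping[int, int] | None = None,
    w_min: int = DEFAULT_W_MIN,
    w_max: int = DEFAULT_W_MAX,
) -> int:
    """Window length for a continuity grade (magnitude rule, clamped).

    Grades of equal magnitude share a length: strong anti-persistence is
    as informative about memory as strong persistence.
    """
    mapping = dict(DEFAULT_GRADE_MAPPING if mapping is None else mapping)
    mag = abs(int(grade))
    if mag not in mapping:
        raise KeyError(f"grade magnitude {mag} missing from mapping")
    return int(np.clip(mapping[mag], w_min, w_max))
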