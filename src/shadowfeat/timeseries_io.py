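"""Data model and CSV I/O for multivariate sensor time series.

A :class:`SensorSeries` holds an N x M matrix of real-valued sensor
readings (rows are time-ordered instances, columns are features such as
the x/y/z axes of an accelerometer), optional per-row class labels and
optional timestamps. Shadow outputs live in :class:`ShadowSeries`, whose
leading warm-up slots are marked unknown; unknown cells serialize to the
literal token ``"?"`` in CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Suffix appended to a feature name to form its shadow-feature name.
SHADOW_SUFFIX = "_shadow"

#: Token written for unknown (warm-up) cells; also accepted on input.
UNKNOWN_TOKEN = "?"


class SchemaError(ValueError):
    """A column required by the schema is missing or misdeclared."""


class ParseError(ValueError):
    """A cell could not be parsed as a number."""


class SeriesValidationError(ValueError):
    """A SensorSeries invariant is violated."""


@dataclass
class SensorSeries:
    """Time-ordered multivariate sensor readings with optional labels.

    Parameters
    ----------
    values : (N, M) float array
        One row per instance, one column per feature.
    feature_names : sequence of M unique strings
    timestamps : (N,) float array, optional
        Seconds (or sample indices). Defaults to 0..N-1 index time.
    labels : sequence of N strings, optional
        Per-row activity class.
    sampling_rate : float, optional
        Nominal rate in Hz.
    """

    values: np.ndarray
    feature_names: list[str]
    timestamps: np.ndarray | None = None
    labels: np.ndarray | None = None
    sampling_rate: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SeriesValidationError("values must be a 2-D array")
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise SeriesValidationError("need at least one row and one feature")
        self.feature_names = [str(f) for f in self.feature_names]
        if len(self.feature_names) != m:
            raise SeriesValidationError(
                f"{len(self.feature_names)} feature names for {m} columns"
            )
        if len(set(self.feature_names)) != m:
            raise SeriesValidationError("feature names must be unique")
        for name in self.feature_names:
            if name.endswith(SHADOW_SUFFIX):
                raise SeriesValidationError(
                    f"feature name {name!r} collides with the reserved "
                    f"shadow suffix {SHADOW_SUFFIX!r}"
                )
        if self.timestamps is None:
            self.timestamps = np.arange(n, dtype=float)
        else:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.shape != (n,):
                raise SeriesValidationError("timestamps must have length N")
            # Monotonicity is report-only (validate_series); CSV ingestion
            # rejects duplicated timestamps at parse time.
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape != (n,):
                raise SeriesValidationError("labels must have length N")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def feature(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def head(self, n: int) -> "SensorSeries":
        """First ``n`` rows as a new series (used for calibration spans)."""
        return replace(
            self,
            values=self.values[:n].copy(),
            timestamps=self.timestamps[:n].copy(),
            labels=None if self.labels is None else self.labels[:n].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "timestamp", self.timestamps)
        if self.labels is not None:
            df["class"] = self.labels
        return df


@dataclass
class ShadowSeries:
    """Shadow-feature values aligned row-for-row with their source series.

    ``unknown_mask`` is true exactly on each column's leading warm-up
    slots (the first base_window - 1 rows), where no full window of past
    data exists yet.
    """

    values: np.ndarray
    unknown_mask: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.unknown_mask = np.asarray(self.unknown_mask, dtype=bool)
        if self.values.shape != self.unknown_mask.shape:
            raise SeriesValidationError("values/unknown_mask shape mismatch")
        if len(self.feature_names) != self.values.shape[1]:
            raise SeriesValidationError("feature name count mismatch")
        known = ~self.unknown_mask
        if not np.all(np.isfinite(self.values[known])):
            raise SeriesValidationError("non-finite value outside warm-up")


def read_sensor_csv(
    path: str | Path,
    schema: Mapping[str, object] | None = None,
) -> SensorSeries:
    """Read a sensor CSV into a validated :class:`SensorSeries`.

    ``schema`` maps column roles to names: ``timestamp`` (a column name,
    or ``"index"`` for implicit 0..N-1 timing), ``features`` (list of
    column names; default: every non-timestamp, non-label column), and
    ``label`` (column name or None; default: a trailing column named
    ``class``/``label``/``activity`` if present). ``"?"`` and empty cells
    become NaN.
    """
    path = Path(path)
    schema = dict(schema or {})
    # only "?" and empty cells are unknown; strings like "null" are
    # legitimate labels, so pandas' default NA list is disabled
    df = pd.read_csv(path, na_values=[UNKNOWN_TOKEN, ""],
                     keep_default_na=False, skipinitialspace=True,
                     float_precision="round_trip")
    cols = list(df.columns)

    ts_col = schema.get("timestamp")
    if ts_col is None:
        ts_col = "timestamp" if "timestamp" in cols else "index"
    if ts_col != "index" and ts_col not in cols:
        raise SchemaError(f"timestamp column {ts_col!r} not in {cols}")

    label_col = schema.get("label", "__auto__")
    if label_col == "__auto__":
        label_col = next(
            (c for c in ("class", "label", "activity") if c in cols), None
        )
    if label_col is not None and label_col not in cols:
        raise SchemaError(f"label column {label_col!r} not in {cols}")

    feats = schema.get("features")
    if feats is None:
        feats = [c for c in cols if c not in (ts_col, label_col)]
    else:
        feats = list(feats)
        missing = [c for c in feats if c not in cols]
        if missing:
            raise SchemaError(f"feature columns {missing} not in {cols}")
        if label_col in feats:
            raise SchemaError(f"label column {label_col!r} listed as feature")

    values = np.empty((len(df), len(feats)), dtype=float)
    for j, c in enumerate(feats):
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.isna() & df[c].notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ParseError(
                f"non-numeric value {df[c].iloc[row]!r} in column {c!r} "
                f"at data row {row}"
            )
        values[:, j] = col.to_numpy()

    timestamps = None
    if ts_col != "index":
        ts = pd.to_numeric(df[ts_col], errors="coerce")
        if ts.isna().any():
            row = int(np.argmax(ts.isna().to_numpy()))
            raise ParseError(f"non-numeric timestamp at data row {row}")
        tvals = ts.to_numpy(dtype=float)
        if len(tvals) > 1 and np.any(np.diff(tvals) == 0):
            raise SeriesValidationError("duplicated timestamp in input")
        timestamps = tvals

    labels = None
    if label_col is not None:
        labels = df[label_col].astype(str).to_numpy(dtype=object)

    return SensorSeries(values=values, feature_names=feats,
                        timestamps=timestamps, labels=labels)


def write_sensor_csv(
    series: SensorSeries | pd.DataFrame,
    path: str | Path,
    include_timestamp: bool = True,
) -> None:
    """Write a series (or an augmented table) to CSV.

    NaN cells — the in-memory representation of unknown warm-up slots —
    are written as the literal token ``"?"``.
    """
    if isinstance(series, SensorSeries):
        df = series.to_frame()
        if not include_timestamp:
            df = df.drop(columns=["timestamp"])
    else:
        df = series
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, index=False, na_rep=UNKNOWN_TOKEN, float_format="%.17g")


def validate_series(series: SensorSeries) -> dict:
    """Report-only health check of a series; never mutates its input.

    Returns a dict with monotonicity violations, NaN count, the inferred
    sampling rate (reciprocal of the median timestep) and the jitter
    fraction (share of timesteps deviating > 1% from the median).
    """
    ts = series.timestamps
    dt = np.diff(ts)
    viol = np.flatnonzero(dt <= 0)
    report: dict = {
        "n_samples": series.n_samples,
        "n_features": series.n_features,
        "monotonicity_violations": [int(i) + 1 for i in viol],
        "nan_count": int(np.isnan(series.values).sum()),
    }
    pos = dt[dt > 0]
    if pos.size:
        med = float(np.median(pos))
        report["inferred_rate_hz"] = 1.0 / med
        report["jitter_fraction"] = float(
            np.mean(np.abs(pos - med) > 0.01 * med)
        )
    else:
        report["inferred_rate_hz"] = None
        report["jitter_fraction"] = None
    return report
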