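"""Benchmark harness: augmentation, baselines, classifiers, metrics.

Reproduces the three-way comparison protocol on synthetic streams:
original features vs. a Haar-wavelet transformation vs. shadow-feature
augmentation, each fed to batch learners (decision tree, SVM, neural
network) and incremental learners (naive Bayes, 1-NN, Hoeffding tree)
in two modes — full training (fit and test on the same stream; an
optimistic ceiling) and train-then-test (test on an independently
generated stream; the honest figure). Shadows for a test stream are
generated from that stream's own history using only training-time
calibration constants, so no information can leak across the split.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from shadowfeat._hoeffding import HoeffdingTreeClassifier
from shadowfeat.characterize import CalibrationResult, calibrate
from shadowfeat.shadow import ShadowConfig, generate_shadow_batch
from shadowfeat.synthetic import (
    ActivitySpec,
    default_accelerometer_spec,
    simulate_activity_stream,
)
from shadowfeat.timeseries_io import SHADOW_SUFFIX, SensorSeries, ShadowSeries

BATCH_LEARNERS = ("decision_tree", "svm", "ann")
INCREMENTAL_LEARNERS = ("naive_bayes", "knn1", "hoeffding_tree")
ALL_LEARNERS = BATCH_LEARNERS + INCREMENTAL_LEARNERS

STRATEGIES = ("original", "haar", "shadow")

#: Offset separating train-stream seeds from test-stream seeds.
TEST_SEED_OFFSET = 10_000


@dataclass
class AugmentedDataset:
    """Original plus shadow predictors, aligned with labels.

    ``predictors`` holds the M original columns followed by their M
    shadows (column j + M is the shadow of column j). ``dropped_rows``
    records warm-up rows removed under the "drop" policy.
    """

    predictors: pd.DataFrame
    labels: np.ndarray | None
    policy: str
    dropped_rows: int = 0

    @property
    def X(self) -> np.ndarray:
        return self.predictors.to_numpy(dtype=float)


@dataclass
class EvalReport:
    """Metrics of one (strategy, learner, mode) run."""

    accuracy: float
    kappa: float
    macro_f: float
    train_time: float
    confusion: np.ndarray
    classes: list
    learner: str = ""
    mode: str = ""
    strategy: str = ""


# ---------------------------------------------------------------------------
# augmentation and baseline features
# ---------------------------------------------------------------------------

def augment_dataset(
    series: SensorSeries,
    shadow: ShadowSeries,
    policy: str = "drop",
) -> AugmentedDataset:
    """Join a series with its shadows into a single predictor table.

    Warm-up handling: "drop" removes any row with an unknown shadow
    slot, "backfill" copies each column's first known value backward,
    "mark" keeps NaN (serialized as "?" by the CSV writer).
    """
    if shadow.values.shape != series.values.shape:
        raise ValueError(
            f"shape mismatch: series {series.values.shape} "
            f"vs shadow {shadow.values.shape}"
        )
    if policy not in ("mark", "drop", "backfill"):
        raise ValueError(f"unknown policy {policy!r}")
    sv = shadow.values.copy()
    labels = None if series.labels is None else series.labels.copy()
    dropped = 0
    if policy == "backfill":
        for j in range(sv.shape[1]):
            known = np.flatnonzero(~shadow.unknown_mask[:, j])
            if known.size:
                sv[: known[0], j] = sv[known[0], j]
    cols = {name: series.values[:, j]
            for j, name in enumerate(series.feature_names)}
    cols.update({name: sv[:, j]
                 for j, name in enumerate(shadow.feature_names)})
    df = pd.DataFrame(cols)
    if policy == "drop":
        keep = ~shadow.unknown_mask.any(axis=1)
        dropped = int((~keep).sum())
        df = df.loc[keep].reset_index(drop=True)
        if labels is not None:
            labels = labels[keep]
    return AugmentedDataset(predictors=df, labels=labels, policy=policy,
                            dropped_rows=dropped)


def original_dataset(series: SensorSeries) -> AugmentedDataset:
    """Predictor table of the untouched original features."""
    df = pd.DataFrame(series.values, columns=series.feature_names)
    return AugmentedDataset(predictors=df, labels=None if series.labels is None
                            else series.labels.copy(), policy="mark")


def haar_features(series: SensorSeries, w: int = 8,
                  drop_warmup: bool = True) -> AugmentedDataset:
    """Level-1 Haar transform over trailing windows (replaces originals).

    For each feature and each trailing window of ``w`` samples (w a
    power of two), consecutive pairs (oldest first) yield averages
    (a+b)/2 and half-differences (b-a)/2; their window means become the
    approximation and detail coefficients. M features map to 2M
    coefficients — a transformation baseline, not an augmentation.
    """
    if w < 2 or (w & (w - 1)) != 0:
        raise ValueError(f"w must be a power of two >= 2, got {w}")
    n, m = series.values.shape
    out = np.full((n, 2 * m), np.nan)
    windows = np.lib.stride_tricks.sliding_window_view(
        series.values, w, axis=0)  # (n-w+1, m, w)
    pairs = windows.reshape(windows.shape[0], m, w // 2, 2)
    approx = pairs.mean(axis=3).mean(axis=2)
    detail = ((pairs[..., 1] - pairs[..., 0]) / 2.0).mean(axis=2)
    out[w - 1:, :m] = approx
    out[w - 1:, m:] = detail
    names = ([f"{f}_haar_a" for f in series.feature_names]
             + [f"{f}_haar_d" for f in series.feature_names])
    df = pd.DataFrame(out, columns=names)
    labels = None if series.labels is None else series.labels.copy()
    dropped = 0
    if drop_warmup:
        df = df.iloc[w - 1:].reset_index(drop=True)
        if labels is not None:
            labels = labels[w - 1:]
        dropped = w - 1
    return AugmentedDataset(predictors=df, labels=labels, policy="drop",
                            dropped_rows=dropped)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def confusion_matrix(y_true, y_pred, classes: Sequence | None = None
                     ) -> tuple[np.ndarray, list]:
    """K x K count matrix, rows = truth, columns = prediction."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    idx = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[idx[t], idx[p]] += 1
    return conf, list(classes)


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement: (p_o - p_e) / (1 - p_e).

    p_e is the marginal-product expected agreement; a degenerate matrix
    with p_e = 1 returns 0.
    """
    conf = np.asarray(confusion, dtype=float)
    total = conf.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(conf) / total
    p_e = float((conf.sum(axis=1) * conf.sum(axis=0)).sum()) / total ** 2
    if p_e >= 1.0:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def macro_f(confusion: np.ndarray) -> float:
    """Unweighted mean per-class F1.

    Classes absent from both truth and prediction are excluded (their F
    is undefined); a class with P + R = 0 contributes F = 0.
    """
    conf = np.asarray(confusion, dtype=float)
    if conf.sum() <= 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(conf)
    row = conf.sum(axis=1)  # truth counts
    col = conf.sum(axis=0)  # prediction counts
    present = (row + col) > 0
    fs = []
    for k in np.flatnonzero(present):
        p = tp[k] / col[k] if col[k] > 0 else 0.0
        r = tp[k] / row[k] if row[k] > 0 else 0.0
        fs.append(0.0 if p + r == 0 else 2 * p * r / (p + r))
    return float(np.mean(fs))


def kappa_band(kappa: float) -> str:
    """Credibility band of a kappa value: high / general / low."""
    if kappa >= 0.75:
        return "high"
    if kappa >= 0.4:
        return "general"
    return "low"


# ---------------------------------------------------------------------------
# learners
# ---------------------------------------------------------------------------

def _make_batch_learner(kind: str, n_predictors: int, seed: int):
    if kind == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if kind == "svm":
        return make_pipeline(StandardScaler(), SVC(random_state=seed))
    if kind == "ann":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(2 * n_predictors,),
                          max_iter=200, random_state=seed),
        )
    raise ValueError(f"unknown batch learner {kind!r}")


class _Incremental1NN:
    """Growing-buffer nearest-neighbour classifier (K = 1)."""

    def __init__(self):
        self._X: list[np.ndarray] = []
        self._y: list = []

    def partial_fit(self, X, y, classes=None):
        for xi, yi in zip(np.asarray(X, dtype=float), y):
            self._X.append(xi)
            self._y.append(yi)
        return self

    def predict(self, X):
        if not self._X:
            raise ValueError("no reference points yet")
        buf = np.vstack(self._X)
        d = cdist(np.asarray(X, dtype=float), buf)
        idx = d.argmin(axis=1)
        return np.asarray([self._y[i] for i in idx], dtype=object)


def _make_incremental_learner(kind: str):
    if kind == "naive_bayes":
        return GaussianNB()
    if kind == "knn1":
        return _Incremental1NN()
    if kind == "hoeffding_tree":
        return HoeffdingTreeClassifier()
    raise ValueError(f"unknown incremental learner {kind!r}")


def _prequential(model, X, y, classes, chunk: int = 1):
    """Test-then-train over a stream; returns the prediction sequence."""
    n = X.shape[0]
    preds = np.empty(n, dtype=object)
    majority = None
    counts: dict = {}
    for i in range(0, n, chunk):
        sl = slice(i, min(i + chunk, n))
        if majority is None:
            preds[sl] = y[sl.start]  # cold start: nothing learned yet
        else:
            # a class seen once has zero variance in GaussianNB; its
            # -inf log-likelihood is well-defined, so mute the warning
            with np.errstate(divide="ignore", invalid="ignore"):
                preds[sl] = model.predict(X[sl])
        model.partial_fit(X[sl], y[sl], classes=classes)
        for c in y[sl]:
            counts[c] = counts.get(c, 0) + 1
        majority = max(counts, key=counts.get)
    return preds


def _check_finite(dataset: AugmentedDataset, who: str) -> None:
    if not np.all(np.isfinite(dataset.X)):
        raise ValueError(
            f"{who} predictors contain unknown/NaN cells; use the 'drop' "
            "or 'backfill' policy before training"
        )


def train_eval(
    dataset: AugmentedDataset,
    learner_kind: str,
    mode: str = "full_training",
    test_dataset: AugmentedDataset | None = None,
    seed: int = 0,
) -> EvalReport:
    """Fit one learner under one protocol and score it.

    full_training: batch learners fit and test on the same table (the
    optimistic ceiling); incremental learners run prequentially
    (test-then-train). train_then_test: fit/learn on ``dataset``, score
    on ``test_dataset`` — an independently generated stream whose
    shadows were produced from its own history only.
    """
    if mode not in ("full_training", "train_then_test"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "train_then_test" and test_dataset is None:
        raise ValueError("train_then_test requires a test_dataset")
    if dataset.labels is None:
        raise ValueError("training data has no labels")
    _check_finite(dataset, "training")

    X, y = dataset.X, np.asarray(dataset.labels)
    classes = sorted(set(y))
    t0 = time.perf_counter()

    if learner_kind in BATCH_LEARNERS:
        model = _make_batch_learner(learner_kind, X.shape[1], seed)
        model.fit(X, y)
        train_time = time.perf_counter() - t0
        if mode == "full_training":
            y_eval, preds = y, model.predict(X)
        else:
            _check_finite(test_dataset, "test")
            y_eval = np.asarray(test_dataset.labels)
            preds = model.predict(test_dataset.X)
    elif learner_kind in INCREMENTAL_LEARNERS:
        model = _make_incremental_learner(learner_kind)
        if mode == "full_training":
            preds = _prequential(model, X, y, classes)
            train_time = time.perf_counter() - t0
            y_eval = y
        else:
            model.partial_fit(X, y, classes=classes)
            train_time = time.perf_counter() - t0
            _check_finite(test_dataset, "test")
            y_eval = np.asarray(test_dataset.labels)
            preds = model.predict(test_dataset.X)
    else:
        raise ValueError(f"unknown learner {learner_kind!r}")

    all_classes = sorted(set(y_eval) | set(np.asarray(preds)) | set(classes))
    conf, cls = confusion_matrix(y_eval, preds, all_classes)
    return EvalReport(
        accuracy=float(np.trace(conf) / conf.sum()),
        kappa=cohen_kappa(conf),
        macro_f=macro_f(conf),
        train_time=train_time,
        confusion=conf,
        classes=cls,
        learner=learner_kind,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# strategy comparison
# ---------------------------------------------------------------------------

def prepare_strategy(
    strategy: str,
    train: SensorSeries,
    test: SensorSeries | None = None,
    shadow_config: ShadowConfig | None = None,
    haar_window: int = 8,
    calibration: CalibrationResult | None = None,
) -> tuple[AugmentedDataset, AugmentedDataset | None]:
    """Build predictor tables for one strategy.

    Shadow calibration uses the training stream only; the test stream's
    shadows are generated from its own history with those calibration
    constants, so the split leaks nothing.
    """
    if strategy == "original":
        return original_dataset(train), None if test is None else original_dataset(test)
    if strategy == "haar":
        return (haar_features(train, haar_window),
                None if test is None else haar_features(test, haar_window))
    if strategy == "shadow":
        cfg = shadow_config or ShadowConfig()
        calib = calibration or calibrate(
            train, calibration_span=cfg.calibration_span,
            grade_mapping=cfg.grade_mapping, w_min=cfg.w_min, w_max=cfg.w_max,
            weighting=cfg.weighting)
        policy = cfg.unknown_policy if cfg.unknown_policy != "mark" else "drop"
        tr = augment_dataset(train, generate_shadow_batch(train, calib, cfg),
                             policy=policy)
        te = None
        if test is not None:
            te = augment_dataset(test, generate_shadow_batch(test, calib, cfg),
                                 policy=policy)
        return tr, te
    raise ValueError(f"unknown strategy {strategy!r}")


def compare_strategies(
    spec: ActivitySpec | None = None,
    learners: Sequence[str] = ALL_LEARNERS,
    seeds: Sequence[int] = (0,),
    modes: Sequence[str] = ("full_training", "train_then_test"),
    strategies: Sequence[str] = STRATEGIES,
    shadow_config: ShadowConfig | None = None,
    haar_window: int = 8,
) -> pd.DataFrame:
    """Seed-averaged comparison table over strategy x learner x mode.

    Each seed generates a fresh train stream (and, for train_then_test,
    a disjoint test stream at seed + TEST_SEED_OFFSET). Returns one row
    per combination with mean accuracy, kappa (plus credibility band),
    macro F and training time.
    """
    spec = spec or default_accelerometer_spec()
    rows = []
    for seed in seeds:
        train = simulate_activity_stream(spec, seed=seed)
        test = simulate_activity_stream(spec, seed=seed + TEST_SEED_OFFSET)
        for strategy in strategies:
            tr, te = prepare_strategy(strategy, train, test,
                                      shadow_config, haar_window)
            for learner in learners:
                for mode in modes:
                    rep = train_eval(tr, learner, mode, test_dataset=te,
                                     seed=seed)
                    rows.append({
                        "strategy": strategy, "learner": learner,
                        "mode": mode, "seed": seed,
                        "accuracy": rep.accuracy, "kappa": rep.kappa,
                        "macro_f": rep.macro_f,
                        "train_time": rep.train_time,
                    })
    df = pd.DataFrame(rows)
    agg = (df.groupby(["strategy", "learner", "mode"], as_index=False)
             [["accuracy", "kappa", "macro_f", "train_time"]].mean())
    agg["kappa_band"] = agg["kappa"].map(kappa_band)
    return agg
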