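import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score, f1_score

from shadowfeat.characterize import calibrate
from shadowfeat.evaluate import (
    ALL_LEARNERS,
    AugmentedDataset,
    TEST_SEED_OFFSET,
    augment_dataset,
    cohen_kappa,
    compare_strategies,
    confusion_matrix,
    haar_features,
    kappa_band,
    macro_f,
    original_dataset,
    prepare_strategy,
    train_eval,
)
from shadowfeat._hoeffding import HoeffdingTreeClassifier
from shadowfeat.shadow import ShadowConfig, generate_shadow_batch
from shadowfeat.synthetic import (
    default_skeleton_spec,
    simulate_activity_stream,
    simulate_skeleton_stream,
)
from shadowfeat.timeseries_io import read_sensor_csv, write_sensor_csv

from conftest import manual_calibration


def _expand(conf):
    """Rebuild label sequences from a confusion matrix (for cross-checks)."""
    y_true, y_pred = [], []
    for i in range(conf.shape[0]):
        for j in range(conf.shape[1]):
            y_true += [i] * conf[i, j]
            y_pred += [j] * conf[i, j]
    return y_true, y_pred


class TestKappa:
    def test_hand_oracle(self):
        # p_o = 0.7, p_e = 0.5
        assert cohen_kappa([[40, 10], [20, 30]]) == pytest.approx(0.4)

    def test_perfect_agreement(self):
        assert cohen_kappa(np.diag([5, 7, 9])) == pytest.approx(1.0)

    def test_marginal_independence_is_zero(self):
        rank1 = np.outer([3, 7], [4, 6])
        assert cohen_kappa(rank1) == pytest.approx(0.0)

    def test_matches_sklearn_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            conf = rng.integers(0, 30, size=(3, 3))
            if conf.sum() == 0:
                continue
            y_true, y_pred = _expand(conf)
            assert cohen_kappa(conf) == pytest.approx(
                cohen_kappa_score(y_true, y_pred), abs=1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa(np.zeros((2, 2)))


class TestMacroF:
    def test_per_class_oracle(self):
        conf = np.array([[40, 10], [20, 30]])
        # first class: P = 40/60, R = 40/50 -> F = 16/22
        tp, col, row = 40, 60, 50
        f1_class1 = 2 * (tp / col) * (tp / row) / (tp / col + tp / row)
        assert f1_class1 == pytest.approx(16 / 22)
        y_true, y_pred = _expand(conf)
        assert macro_f(conf) == pytest.approx(
            f1_score(y_true, y_pred, average="macro"))

    def test_diagonal_is_one(self):
        assert macro_f(np.diag([3, 4])) == pytest.approx(1.0)

    def test_absent_class_excluded(self):
        # class 1 never true and never predicted: mean over the other two
        conf = np.array([[10, 0, 0], [0, 0, 0], [0, 0, 10]])
        assert macro_f(conf) == pytest.approx(1.0)

    def test_bands(self):
        assert kappa_band(0.9) == "high"
        assert kappa_band(0.75) == "high"
        assert kappa_band(0.5) == "general"
        assert kappa_band(0.39) == "low"


class TestHaarFeatures:
    def test_constant_series_has_zero_details(self, series_1to10):
        const = series_1to10
        const.values[:] = 4.0
        feats = haar_features(const, w=4, drop_warmup=True)
        assert np.allclose(feats.predictors["x_haar_d"], 0.0)
        assert np.allclose(feats.predictors["x_haar_a"], 4.0)

    def test_alternating_signal_oracle(self):
        from shadowfeat.timeseries_io import SensorSeries
        x = np.tile([1.0, -1.0], 10)
        s = SensorSeries(values=x[:, None], feature_names=["x"])
        feats = haar_features(s, w=2, drop_warmup=True)
        assert np.allclose(feats.predictors["x_haar_a"], 0.0)
        assert np.allclose(np.abs(feats.predictors["x_haar_d"]), 1.0)

    def test_feature_count_doubles(self, small_stream):
        feats = haar_features(small_stream, w=8)
        assert feats.predictors.shape[1] == 2 * small_stream.n_features

    def test_window_must_be_power_of_two(self, small_stream):
        with pytest.raises(ValueError):
            haar_features(small_stream, w=6)


class TestAugmentDataset:
    def test_skeleton_doubles_to_128(self):
        s = simulate_skeleton_stream(default_skeleton_spec(segment_length=40))
        calib = manual_calibration(s.feature_names, base_window=8)
        shadow = generate_shadow_batch(
            s, calib, ShadowConfig(dynamic_window=False, phi_enabled=False))
        aug = augment_dataset(s, shadow, policy="drop")
        assert aug.predictors.shape[1] == 128

    def test_drop_policy_warmup_arithmetic(self, small_stream):
        calib = manual_calibration(small_stream.feature_names, base_window=8)
        shadow = generate_shadow_batch(
            small_stream, calib,
            ShadowConfig(dynamic_window=False, phi_enabled=False))
        aug = augment_dataset(small_stream, shadow, policy="drop")
        assert aug.predictors.shape[0] == small_stream.n_samples - 7
        assert aug.dropped_rows == 7

    def test_shadow_columns_follow_originals(self, small_stream):
        calib = manual_calibration(small_stream.feature_names, base_window=4)
        shadow = generate_shadow_batch(
            small_stream, calib,
            ShadowConfig(dynamic_window=False, phi_enabled=False))
        aug = augment_dataset(small_stream, shadow, policy="drop")
        m = small_stream.n_features
        cols = list(aug.predictors.columns)
        for j in range(m):
            assert cols[j + m] == cols[j] + "_shadow"

    def test_backfill_fills_warmup(self, small_stream):
        calib = manual_calibration(small_stream.feature_names, base_window=8)
        shadow = generate_shadow_batch(
            small_stream, calib,
            ShadowConfig(dynamic_window=False, phi_enabled=False))
        aug = augment_dataset(small_stream, shadow, policy="backfill")
        assert np.isfinite(aug.X).all()
        assert aug.predictors.shape[0] == small_stream.n_samples

    def test_mark_policy_round_trips_through_csv(self, small_stream, tmp_path):
        calib = manual_calibration(small_stream.feature_names, base_window=8)
        shadow = generate_shadow_batch(
            small_stream, calib,
            ShadowConfig(dynamic_window=False, phi_enabled=False))
        aug = augment_dataset(small_stream, shadow, policy="mark")
        p = tmp_path / "aug.csv"
        write_sensor_csv(aug.predictors, p)
        assert "?" in p.read_text()[:2000]
        back = pd.read_csv(p, na_values=["?"], keep_default_na=False)
        assert int(back.isna().sum().sum()) == 7 * small_stream.n_features

    def test_shape_mismatch_rejected(self, small_stream, series_1to10):
        calib = manual_calibration(["x"], base_window=3)
        shadow = generate_shadow_batch(series_1to10, calib, ShadowConfig())
        with pytest.raises(ValueError):
            augment_dataset(small_stream, shadow)


def _separable_dataset(n=1500, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 0.3, (n, 2)), rng.normal(5, 0.3, (n, 2))])
    y = np.array(["a"] * n + ["b"] * n, dtype=object)
    return AugmentedDataset(predictors=pd.DataFrame(X, columns=["p", "q"]),
                            labels=y, policy="drop")


class TestTrainEval:
    def test_separable_classes_are_perfect(self):
        rep = train_eval(_separable_dataset(), "decision_tree",
                         "full_training")
        assert rep.accuracy == 1.0
        assert rep.kappa == pytest.approx(1.0)

    @pytest.mark.parametrize("learner", ALL_LEARNERS)
    def test_every_learner_contract(self, learner):
        tr = _separable_dataset(seed=1)
        te = _separable_dataset(seed=2)
        rep = train_eval(tr, learner, "train_then_test", te)
        assert rep.confusion.sum() == len(te.labels)
        assert rep.accuracy > 0.9  # trivially separable
        assert -1.0 <= rep.kappa <= 1.0 and 0.0 <= rep.macro_f <= 1.0
        assert rep.accuracy == pytest.approx(
            np.trace(rep.confusion) / rep.confusion.sum())

    def test_unknown_learner_rejected(self):
        with pytest.raises(ValueError):
            train_eval(_separable_dataset(), "boosted_stump")

    def test_nan_predictors_rejected(self):
        ds = _separable_dataset()
        ds.predictors.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="drop"):
            train_eval(ds, "decision_tree")

    def test_train_then_test_requires_test_set(self):
        with pytest.raises(ValueError):
            train_eval(_separable_dataset(), "decision_tree",
                       "train_then_test")


class TestHoeffdingTree:
    def test_learns_separable_stream(self):
        rng = np.random.default_rng(4)
        n = 2000
        X = np.vstack([rng.normal(0, 0.5, (n, 3)), rng.normal(4, 0.5, (n, 3))])
        y = np.array([0] * n + [1] * n)
        order = rng.permutation(2 * n)
        X, y = X[order], y[order]
        model = HoeffdingTreeClassifier()
        model.partial_fit(X[:3000], y[:3000], classes=[0, 1])
        acc = (model.predict(X[3000:]) == y[3000:]).mean()
        assert acc > 0.95

    def test_predict_before_fit_rejected(self):
        with pytest.raises(ValueError):
            HoeffdingTreeClassifier().predict(np.zeros((1, 2)))


class TestLeakageStructure:
    def test_test_shadows_depend_only_on_test_history(self, tiny_spec):
        """Calibration constants come from train; altering train labels or
        later test rows cannot change earlier test shadows."""
        train = simulate_activity_stream(tiny_spec, seed=0)
        test = simulate_activity_stream(tiny_spec, seed=TEST_SEED_OFFSET)
        _, te_a = prepare_strategy("shadow", train, test)
        # truncate the test stream: earlier shadow rows must be unchanged
        test_cut = test.head(test.n_samples // 2)
        _, te_b = prepare_strategy("shadow", train, test_cut)
        n = te_b.predictors.shape[0]
        pd.testing.assert_frame_equal(te_a.predictors.iloc[:n],
                                      te_b.predictors)


class TestCompareStrategies:
    def test_full_cartesian_table(self, tiny_spec):
        table = compare_strategies(tiny_spec, learners=ALL_LEARNERS,
                                   seeds=(0,))
        assert len(table) == 3 * 6 * 2
        assert set(table["kappa_band"]) <= {"high", "general", "low"}

    def test_deterministic_given_seeds(self, tiny_spec):
        kw = dict(learners=("decision_tree",), seeds=(0, 1))
        a = compare_strategies(tiny_spec, **kw)
        b = compare_strategies(tiny_spec, **kw)
        pd.testing.assert_frame_equal(a.drop(columns="train_time"),
                                      b.drop(columns="train_time"))
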