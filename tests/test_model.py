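"""Boosted-tree r_i regressors: splitting, training, metrics, refitting."""

import numpy as np
import pandas as pd
import pytest

from cnlri import (
    CNL_PRESET,
    DESCRIPTOR_PRESET,
    SplitSpec,
    cross_validate,
    evaluate,
    load_model,
    predict,
    refit_top_features,
    ri_classes,
    save_model,
    stratified_split,
    train,
)


def linear_problem(n=200, p=8, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = 600.0 + 120.0 * X[:, 0] + 60.0 * X[:, 1] + rng.normal(0, noise, n)
    return pd.DataFrame(X, columns=[f"d{j}" for j in range(p)]), y


class TestStratifiedSplit:
    def test_class_proportions_within_one_sample(self):
        rng = np.random.default_rng(0)
        labels = np.concatenate(
            [rng.uniform(200, 440, 34), rng.uniform(440, 700, 33), rng.uniform(700, 1041, 33)]
        )
        tr, te = stratified_split(labels, SplitSpec(train_fraction=0.85, seed=1))
        assert len(tr) + len(te) == 100
        assert not set(tr) & set(te)
        classes = ri_classes(labels)
        for c in range(3):
            n_c = (classes == c).sum()
            n_train_c = (classes[tr] == c).sum()
            assert abs(n_train_c - 0.85 * n_c) <= 1

    def test_single_class_degenerates_to_random_split(self):
        labels = np.full(40, 300.0) + np.arange(40) * 0.1
        tr, te = stratified_split(labels, SplitSpec(train_fraction=0.75, seed=2))
        assert len(tr) == 30 and len(te) == 10

    def test_deterministic_under_seed(self):
        labels = np.random.default_rng(3).uniform(200, 1041, 60)
        a = stratified_split(labels, SplitSpec(seed=9))
        b = stratified_split(labels, SplitSpec(seed=9))
        np.testing.assert_array_equal(a[0], b[0])

    def test_nonfinite_labels_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.array([300.0, np.nan]), SplitSpec())


class TestTrain:
    def test_step_function_recovered_exactly(self):
        # labels are 500 + 300 * binary feature: a single split represents it
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"bit": rng.integers(0, 2, 200).astype(float)})
        y = 500.0 + 300.0 * X["bit"].to_numpy()
        model = train(X.iloc[:150], y[:150], DESCRIPTOR_PRESET)
        rmse = evaluate(predict(model, X.iloc[150:]), y[150:]).rmse
        assert rmse < 5.0

    def test_training_is_deterministic(self):
        X, y = linear_problem(noise=20.0)
        m1 = train(X, y, DESCRIPTOR_PRESET.with_seed(5))
        m2 = train(X, y, DESCRIPTOR_PRESET.with_seed(5))
        np.testing.assert_array_equal(predict(m1, X), predict(m2, X))
        assert m1.training_fingerprint == m2.training_fingerprint

    def test_early_stopping_bounds_tree_count(self):
        X, y = linear_problem(noise=50.0)
        model = train(
            X.iloc[:150], y[:150], CNL_PRESET, validation=(X.iloc[150:], y[150:])
        )
        assert model.best_iteration is not None
        assert model.best_iteration <= CNL_PRESET.iterations

    @pytest.mark.parametrize(
        "labels", [np.full(50, 420.0), np.r_[np.full(49, 1.0), np.nan]]
    )
    def test_degenerate_labels_rejected(self, labels):
        X = pd.DataFrame({"d": np.arange(50, dtype=float)})
        with pytest.raises(ValueError):
            train(X, labels, DESCRIPTOR_PRESET)

    def test_used_features_subset_of_features(self):
        X, y = linear_problem()
        model = train(X, y, DESCRIPTOR_PRESET)
        assert set(model.used_features) <= set(model.feature_names)
        assert "d0" in model.used_features  # the dominant signal carrier


class TestPredict:
    def test_column_order_aligned_by_name(self):
        X, y = linear_problem()
        model = train(X, y, DESCRIPTOR_PRESET)
        shuffled = X[list(reversed(X.columns))]
        np.testing.assert_array_equal(predict(model, X), predict(model, shuffled))

    def test_missing_column_error_lists_difference(self):
        X, y = linear_problem()
        model = train(X, y, DESCRIPTOR_PRESET)
        with pytest.raises(ValueError, match="d0"):
            predict(model, X.drop(columns=["d0"]))

    def test_single_row(self):
        X, y = linear_problem()
        model = train(X, y, DESCRIPTOR_PRESET)
        assert predict(model, X.iloc[:1]).shape == (1,)


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([300.0, 500.0, 900.0])
        rep = evaluate(y, y)
        assert (rep.r_squared, rep.rmse, rep.max_error) == (1.0, 0.0, 0.0)

    def test_constant_offset(self):
        y = np.linspace(200, 1000, 20)
        rep = evaluate(y + 10.0, y)
        assert rep.rmse == pytest.approx(10.0)
        assert rep.max_error == pytest.approx(10.0)

    def test_hand_evaluated_r_squared(self):
        # truth [0,10], predictions [0,0]: R^2 = 1 - 100/50 = -1
        rep = evaluate(np.array([0.0, 0.0]), np.array([0.0, 10.0]))
        assert rep.r_squared == pytest.approx(-1.0)
        assert rep.rmse == pytest.approx(np.sqrt(50.0))

    def test_zero_variance_truth_flagged(self):
        rep = evaluate(np.array([1.0, 2.0]), np.array([5.0, 5.0]))
        assert np.isnan(rep.r_squared)


class TestCrossValidate:
    def test_folds_partition_rows(self):
        X, y = linear_problem(n=100, noise=30.0)
        y = 200 + (y - y.min()) / np.ptp(y) * 800
        reports, summary = cross_validate(X, y, DESCRIPTOR_PRESET, k=5)
        assert len(reports) == 5
        assert sum(r.n for r in reports) == 100
        assert "r_squared_mean" in summary

    def test_clean_signal_gives_high_fold_r2(self):
        # noise-free piecewise-constant signal, exactly representable by trees
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(150, 5)), columns=[f"d{j}" for j in range(5)])
        y = 300.0 + 400.0 * (X["d0"] > 0) + 100.0 * (X["d1"] > 0)
        _, summary = cross_validate(X, y.to_numpy(), DESCRIPTOR_PRESET, k=5)
        assert summary["r_squared_mean"] > 0.95

    def test_permuted_labels_destroy_r2(self):
        X, y = linear_problem(n=150, noise=0.0)
        y_perm = np.random.default_rng(0).permutation(y)
        _, summary = cross_validate(X, y_perm, DESCRIPTOR_PRESET, k=5)
        assert summary["r_squared_mean"] <= 0.1

    def test_n_smaller_than_k_errors(self):
        X, y = linear_problem(n=12)
        with pytest.raises(ValueError):
            cross_validate(X.iloc[:3], y[:3], DESCRIPTOR_PRESET, k=5)


class TestRefitTopFeatures:
    def test_concentrated_signal_survives_selection(self):
        X, y = linear_problem(n=300, p=20, noise=10.0)
        full = train(X.iloc[:200], y[:200], DESCRIPTOR_PRESET)
        slim = refit_top_features(full, X.iloc[:200], y[:200], top_k=3)
        r2_full = evaluate(predict(full, X.iloc[200:]), y[200:]).r_squared
        r2_slim = evaluate(predict(slim, X.iloc[200:]), y[200:]).r_squared
        assert len(slim.feature_names) == 3
        assert r2_slim >= r2_full - 0.05

    def test_top_k_all_features_is_noop_selection(self):
        X, y = linear_problem(n=120, noise=5.0)
        full = train(X, y, DESCRIPTOR_PRESET)
        refit = refit_top_features(full, X, y, top_k=X.shape[1])
        assert set(refit.feature_names) == set(full.feature_names)

    def test_top_k_exceeding_feature_count_errors(self):
        X, y = linear_problem(n=50)
        full = train(X, y, DESCRIPTOR_PRESET)
        with pytest.raises(ValueError):
            refit_top_features(full, X, y, top_k=100)


def test_model_roundtrip_through_disk(tmp_path):
    X, y = linear_problem(n=80, noise=10.0)
    model = train(X, y, DESCRIPTOR_PRESET)
    save_model(model, tmp_path / "m.joblib")
    back = load_model(tmp_path / "m.joblib")
    np.testing.assert_array_equal(predict(back, X), predict(model, X))
    assert (tmp_path / "m.joblib.json").exists()
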