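import numpy as np
import pandas as pd
import pytest

from dynfet.modeling import (
    LogisticModel,
    balanced_class_weights,
    evaluate,
    fit_final_model,
    pcc_filter,
    predict_probability,
    rfe_rank,
    select_n_features,
    standardize,
    stratified_split,
)


def labelled_cohort(n_mut, n_wt):
    ids = [f"M{i}" for i in range(n_mut)] + [f"W{i}" for i in range(n_wt)]
    return pd.Series([1] * n_mut + [0] * n_wt, index=ids)


class TestStratifiedSplit:
    def test_159_patient_cohort_arithmetic(self):
        labels = labelled_cohort(128, 31)
        split = stratified_split(labels, 0.7, seed=0)
        train = labels[list(split.train_ids)]
        test = labels[list(split.test_ids)]
        assert len(train) == 112 and len(test) == 47
        assert (train == 0).sum() == 22 and (train == 1).sum() == 90
        assert (test == 0).sum() == 9 and (test == 1).sum() == 38

    def test_single_class_split(self):
        labels = pd.Series([1] * 10)
        split = stratified_split(labels, 0.7, seed=1)
        assert len(split.train_ids) == 7 and len(split.test_ids) == 3

    def test_deterministic_given_seed(self):
        labels = labelled_cohort(30, 10)
        assert stratified_split(labels, 0.7, 5) == stratified_split(labels, 0.7, 5)
        assert stratified_split(labels, 0.7, 5) != stratified_split(labels, 0.7, 6)

    def test_rejects_bad_fraction(self):
        with pytest.raises(ValueError):
            stratified_split(labelled_cohort(4, 4), 1.2, 0)


class TestStandardize:
    def test_two_point_column(self):
        train = pd.DataFrame({"a": [1.0, 3.0]})
        _, train_z, _ = standardize(train)
        assert train_z["a"].tolist() == [-1.0, 1.0]

    def test_constant_column_dropped(self):
        train = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        params, train_z, _ = standardize(train)
        assert "b" in params.dropped and "b" not in train_z.columns

    def test_training_columns_become_standard(self):
        rng = np.random.default_rng(0)
        train = pd.DataFrame(rng.normal(3, 2, (50, 4)), columns=list("abcd"))
        _, train_z, _ = standardize(train)
        assert np.allclose(train_z.mean(), 0, atol=1e-12)
        assert np.allclose(train_z.std(ddof=0), 1, atol=1e-12)

    def test_params_ignore_test_data(self):
        rng = np.random.default_rng(1)
        train = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        test = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        p1, _, _ = standardize(train, test)
        p2, _, _ = standardize(train, test * 100 + 7)
        pd.testing.assert_series_equal(p1.mean, p2.mean)
        pd.testing.assert_series_equal(p1.sd, p2.sd)


class TestPccFilter:
    def test_duplicate_column_keeps_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=30)
        df = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=30)})
        assert pcc_filter(df) == ["a", "c"]

    def test_three_mutual_duplicates_one_survivor(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=30)
        df = pd.DataFrame({"x": a, "y": 2 * a + 1, "z": -a})
        survivors = pcc_filter(df)
        assert survivors == ["x"]

    def test_uncorrelated_features_untouched(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(100, 5)), columns=list("abcde"))
        assert pcc_filter(df) == list("abcde")

    def test_survivors_pairwise_below_threshold(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(60, 4))
        df = pd.DataFrame(
            np.hstack([base, base + rng.normal(scale=1e-4, size=base.shape)]),
            columns=[f"f{i}" for i in range(8)],
        )
        survivors = pcc_filter(df, 0.99)
        corr = np.abs(np.corrcoef(df[survivors].to_numpy(), rowvar=False))
        np.fill_diagonal(corr, 0)
        assert corr.max() <= 0.99


class TestBalancedWeights:
    def test_90_22_training_cohort(self):
        labels = labelled_cohort(90, 22)
        w = balanced_class_weights(labels)
        assert w[1] == pytest.approx(112 / (2 * 90))
        assert w[0] == pytest.approx(112 / (2 * 22))
        assert w[1] * 90 == pytest.approx(w[0] * 22)

    def test_balanced_classes_unit_weights(self):
        w = balanced_class_weights(labelled_cohort(15, 15))
        assert w == {0: 1.0, 1: 1.0}


class TestRFE:
    @staticmethod
    def planted_data(n=200, n_noise=8, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.random(n) < 0.7
        signal = y * 2.0 + rng.normal(scale=0.5, size=n)
        X = pd.DataFrame(
            {"signal": signal, **{f"noise{i:02d}": rng.normal(size=n) for i in range(n_noise)}}
        )
        return X, pd.Series(y.astype(int))

    def test_informative_feature_survives_to_the_end(self):
        X, y = self.planted_data()
        order = rfe_rank(X, y)
        assert order[-1] == "signal"

    def test_elimination_order_covers_all_features(self):
        X, y = self.planted_data()
        order = rfe_rank(X, y)
        assert sorted(order) == sorted(X.columns)
        assert len(order) == X.shape[1]

    def test_selection_curve_has_one_entry_per_candidate(self):
        X, y = self.planted_data(n=100, n_noise=5)
        n_sel, curve = select_n_features(X, y, folds=5, seed=0)
        assert len(curve) == X.shape[1]
        assert 1 <= n_sel <= X.shape[1]

    def test_planted_signals_recovered_across_seeds(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 200
            y = (rng.random(n) < 0.7).astype(int)
            X = pd.DataFrame(
                rng.normal(size=(n, 50)), columns=[f"n{i:02d}" for i in range(50)]
            )
            for name in ("s1", "s2", "s3"):
                X[name] = y * 1.5 + rng.normal(scale=0.8, size=n)
            n_sel, _ = select_n_features(X, pd.Series(y), folds=10, seed=seed)
            selected = rfe_rank(X, pd.Series(y))[-n_sel:]
            if len({"s1", "s2", "s3"} & set(selected)) >= 2:
                hits += 1
        assert hits >= 0.8 * n_seeds

    def test_fold_missing_a_class_is_an_error(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(12, 3)), columns=list("abc"))
        y = pd.Series([1] * 10 + [0] * 2)
        with pytest.raises(ValueError, match="fewer folds"):
            select_n_features(X, y, folds=10, seed=0)


class TestFinalModelAndPrediction:
    def test_antisymmetric_data_gives_zero_intercept(self):
        X = pd.DataFrame({"a": [-2.0, -1.0, 1.0, 2.0]})
        y = pd.Series([0, 0, 1, 1])
        model = fit_final_model(X, y)
        assert model.intercept == pytest.approx(0.0, abs=1e-6)

    def test_label_flip_flips_coefficients(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        y = pd.Series((X["a"] + rng.normal(scale=0.5, size=60) > 0).astype(int))
        m1 = fit_final_model(X, y)
        m2 = fit_final_model(X, 1 - y)
        assert np.allclose(m1.theta, -m2.theta, atol=1e-4)

    def test_refit_is_deterministic(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(40, 4)))
        X.columns = list("abcd")
        y = pd.Series(rng.integers(0, 2, 40))
        assert np.allclose(fit_final_model(X, y).theta, fit_final_model(X, y).theta, atol=1e-8)

    def test_zero_model_predicts_half_and_negative(self):
        model = LogisticModel(("a",), np.array([0.0]), 0.0, {0: 1, 1: 1})
        p, label = predict_probability(model, {"a": 3.0})
        assert p == 0.5 and label == 0  # strict > rule

    def test_intercept_0599_with_features_at_zero(self):
        model = LogisticModel(
            ("f1", "f2"), np.array([1.508, 1.404]), 0.599, {0: 1, 1: 1}
        )
        p, label = predict_probability(model, {"f1": 0.0, "f2": 0.0})
        assert p == pytest.approx(1 / (1 + np.exp(-0.599)))
        assert round(p, 4) == 0.6454 and label == 1

    def test_logistic_symmetry(self):
        model = LogisticModel(("a", "b"), np.array([0.7, -1.2]), 0.0, {0: 1, 1: 1})
        p1, _ = predict_probability(model, {"a": 1.0, "b": 2.0})
        p2, _ = predict_probability(model, {"a": -1.0, "b": -2.0})
        assert p1 + p2 == pytest.approx(1.0)

    def test_missing_feature_is_named(self):
        model = LogisticModel(("needed",), np.array([1.0]), 0.0, {0: 1, 1: 1})
        with pytest.raises(KeyError, match="needed"):
            predict_probability(model, {"other": 1.0})


class TestEvaluate:
    def test_perfect_separation(self):
        r = evaluate(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]), n_bootstrap=50)
        assert r.metrics["auc"] == 1.0
        assert r.metrics["sensitivity"] == 1.0
        assert r.metrics["specificity"] == 1.0

    def test_auc_matches_pairwise_count(self):
        probs = np.array([0.9, 0.6, 0.4])
        labels = np.array([1, 0, 1])
        # brute force over positive-negative pairs: (0.9>0.6) + (0.4<0.6) -> 1/2
        r = evaluate(probs, labels, n_bootstrap=10)
        assert r.metrics["auc"] == pytest.approx(0.5)

    def test_auc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(0)
        probs = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        a1 = evaluate(probs, labels, n_bootstrap=10).metrics["auc"]
        a2 = evaluate(1 / (1 + np.exp(-5 * probs)), labels, n_bootstrap=10).metrics["auc"]
        assert a1 == pytest.approx(a2)

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(1)
        aucs = []
        for _ in range(30):
            probs = rng.random(100)
            labels = rng.integers(0, 2, 100)
            if len(np.unique(labels)) < 2:
                continue
            aucs.append(evaluate(probs, labels, n_bootstrap=2).metrics["auc"])
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_cis_bracket_point_estimates(self):
        rng = np.random.default_rng(2)
        probs = np.clip(rng.normal(0.5, 0.2, 80), 0, 1)
        labels = (probs + rng.normal(scale=0.3, size=80) > 0.5).astype(int)
        r = evaluate(probs, labels, n_bootstrap=300, seed=3)
        for k in ("auc", "accuracy", "sensitivity", "specificity"):
            lo, hi = r.ci95[k]
            assert lo <= r.metrics[k] <= hi

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError, match="both classes"):
            evaluate(np.array([0.2, 0.8]), np.array([1, 1]), n_bootstrap=5)

    def test_bootstrap_is_seeded(self):
        probs = np.random.default_rng(4).random(30)
        labels = np.r_[np.ones(15, int), np.zeros(15, int)]
        r1 = evaluate(probs, labels, n_bootstrap=100, seed=9)
        r2 = evaluate(probs, labels, n_bootstrap=100, seed=9)
        assert r1.ci95 == r2.ci95
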