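import numpy as np
import pandas as pd
import pytest

from eegfc.classify import (ClassificationError, DEFAULT_GRID, conditional_shap,
                            feature_importance, fit_l2_logistic, loo_predict,
                            nested_cv, table_to_xy)
from eegfc.recording import GROUP_A, GROUP_B


def separable_cohort(rng, n=18, p=20, shift=2.5, informative=5):
    pos = rng.standard_normal((n, p))
    pos[:, :informative] += shift
    neg = rng.standard_normal((n, p))
    X = np.vstack([pos, neg])
    y = np.r_[np.ones(n, dtype=int), np.zeros(n, dtype=int)]
    return X, y


class TestFitL2Logistic:
    def test_penalty_dominated_limit(self, rng):
        X, y = separable_cohort(rng)
        model = fit_l2_logistic(X, y, strength=1e8)
        assert np.abs(model.coef).max() < 1e-3
        assert np.allclose(model.predict_proba(X), y.mean(), atol=0.01)

    def test_informative_feature_sign(self, rng):
        X = rng.standard_normal((40, 3))
        y = (X[:, 1] > 0).astype(int)
        model = fit_l2_logistic(X, y, strength=1.0)
        assert model.coef[1] > 0
        assert abs(model.coef[1]) > abs(model.coef[0])

    def test_gradient_optimality(self, rng):
        X = rng.standard_normal((30, 5))
        y = (X[:, 0] + 0.3 * rng.standard_normal(30) > 0).astype(int)
        strength = 2.0
        m = fit_l2_logistic(X, y, strength, standardize=False)
        z = X @ m.coef + m.intercept
        s = 1 / (1 + np.exp(-z))
        grad_w = m.coef + (1 / strength) * X.T @ (s - y)
        grad_b = (1 / strength) * np.sum(s - y)
        assert np.sqrt((grad_w ** 2).sum() + grad_b ** 2) < 1e-6

    def test_single_class_rejected(self, rng):
        with pytest.raises(ClassificationError):
            fit_l2_logistic(rng.standard_normal((10, 2)), np.ones(10, int), 1.0)

    def test_nonfinite_rejected(self):
        X = np.array([[1.0, np.inf], [0.0, 1.0], [2.0, 0.0], [1.0, 2.0]])
        with pytest.raises(ClassificationError):
            fit_l2_logistic(X, np.array([0, 1, 0, 1]), 1.0)


class TestNestedCV:
    def test_separable_cohort_high_accuracy(self, rng):
        X, y = separable_cohort(rng)
        report = nested_cv(X, y, seed=0)
        assert len(report.folds) == 6
        assert report.summary()["accuracy"]["mean"] >= 0.95

    def test_metric_consistency_per_fold(self, rng):
        X, y = separable_cohort(rng, shift=1.0)
        report = nested_cv(X, y, seed=1)
        for _, row in report.folds.iterrows():
            # each outer fold holds 3 positives and 3 negatives
            acc = (row.sensitivity * 3 + row.specificity * 3) / 6
            assert row.accuracy == pytest.approx(acc)
            assert 0 <= row.auc <= 1

    def test_determinism(self, rng):
        X, y = separable_cohort(rng, shift=0.8)
        a = nested_cv(X, y, seed=3)
        b = nested_cv(X, y, seed=3)
        pd.testing.assert_frame_equal(a.folds, b.folds)

    def test_shuffled_labels_near_chance(self, rng):
        X, y = separable_cohort(rng)
        accs = [nested_cv(X, np.random.default_rng(i).permutation(y),
                          grid=[0.1, 10.0], seed=i).summary()["accuracy"]["mean"]
                for i in range(10)]
        assert 0.3 < np.mean(accs) < 0.7

    def test_stratification_error_small_class(self, rng):
        X = rng.standard_normal((10, 3))
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            nested_cv(X, y, outer=6, seed=0)


class TestConditionalShap:
    def test_local_accuracy(self, rng):
        X, y = separable_cohort(rng, n=12, p=8)
        model = fit_l2_logistic(X, y, 1.0)
        sv, base = conditional_shap(model, X, X, n_permutations=8, seed=0)
        margins = model.decision_function(X)
        assert np.abs(base + sv.sum(axis=1) - margins).max() < 1e-6

    def test_independent_features_closed_form(self, rng):
        X, y = separable_cohort(rng, n=15, p=6)
        model = fit_l2_logistic(X, y, 1.0)
        Xs = model.standardize(X)
        cov = np.diag(Xs.var(axis=0))
        sv, _ = conditional_shap(model, X, X, covariance=cov)
        closed = (Xs - Xs.mean(axis=0)) * model.coef
        assert np.allclose(sv, closed, atol=1e-10)

    def test_zero_weight_uncorrelated_feature_gets_zero(self, rng):
        X, y = separable_cohort(rng, n=15, p=4)
        model = fit_l2_logistic(X, y, 1.0)
        model.coef[2] = 0.0
        cov = np.diag(model.standardize(X).var(axis=0))
        sv, _ = conditional_shap(model, X, X, covariance=cov)
        assert np.allclose(sv[:, 2], 0.0)

    def test_duplicated_feature_shares_credit_equally(self, rng):
        base_col = rng.standard_normal((40, 1))
        X = np.hstack([base_col, base_col])
        y = (base_col[:, 0] > 0).astype(int)
        model = fit_l2_logistic(X, y, 1.0)
        sv, _ = conditional_shap(model, X, X)
        assert np.allclose(sv[:, 0], sv[:, 1], atol=1e-9)
        margins = model.decision_function(X)
        total = sv.sum(axis=1)
        assert np.allclose(sv[:, 0], total / 2, atol=1e-9)
        assert np.allclose(total + _base(model, X), margins, atol=1e-6)

    def test_small_background_rejected(self, rng):
        X, y = separable_cohort(rng, n=5, p=3)
        model = fit_l2_logistic(X, y, 1.0)
        with pytest.raises(ClassificationError):
            conditional_shap(model, X[:1], X)


def _base(model, X):
    return model.standardize(X).mean(axis=0) @ model.coef + model.intercept


class TestFeatureImportance:
    def test_single_active_feature(self):
        sv = np.zeros((4, 3))
        sv[:, 1] = [1.0, -2.0, 1.5, -0.5]
        rep = feature_importance(sv, ["a", "a", "b", "b"], ["f0", "f1", "f2"])
        assert rep.fi[1] == 1.0
        assert rep.fi[0] == 0.0 and rep.fi[2] == 0.0

    def test_max_fi_is_one(self, rng):
        sv = rng.standard_normal((10, 7))
        rep = feature_importance(sv, ["a"] * 5 + ["b"] * 5, range(7))
        assert rep.fi.max() == pytest.approx(1.0)
        for vec in rep.fi_by_group.values():
            assert vec.max() == pytest.approx(1.0)

    def test_duplication_invariance(self, rng):
        sv = rng.standard_normal((6, 4))
        labels = ["a", "b", "a", "b", "a", "b"]
        r1 = feature_importance(sv, labels, range(4))
        r2 = feature_importance(np.vstack([sv, sv]), labels * 2, range(4))
        assert np.allclose(r1.fi, r2.fi)

    def test_all_zero_rejected(self):
        with pytest.raises(ClassificationError):
            feature_importance(np.zeros((3, 2)), ["a", "b", "a"], ["f0", "f1"])


class TestLOOPredict:
    def test_tiny_identical_rows_all_correct(self):
        X = np.array([[1.0, 0.0], [1.0, 0.0], [-1.0, 0.0], [-1.0, 0.0]])
        y = np.array([1, 1, 0, 0])
        loo = loo_predict(X, y, ["s1", "s2", "s3", "s4"],
                          grid=[1.0], inner=2, seed=0)
        assert loo.misclassified == []
        assert np.all((loo.proba >= 0.5) == y.astype(bool))

    def test_separated_cohort_probabilities_cluster(self, rng):
        X, y = separable_cohort(rng, n=8, p=10, shift=3.0)
        ids = [f"s{i}" for i in range(16)]
        loo = loo_predict(X, y, ids, grid=[0.1, 1.0, 10.0], seed=0)
        assert np.median(loo.proba[y == 1]) > 0.5
        assert np.median(loo.proba[y == 0]) < 0.5
        assert len(loo.misclassified) <= 3

    def test_swapped_profile_subject_misclassified(self, rng):
        X, y = separable_cohort(rng, n=10, p=8, shift=3.5)
        X[0] = X[-1].copy() + 0.01 * rng.standard_normal(8)  # positive label, negative profile
        loo = loo_predict(X, y, [f"s{i}" for i in range(20)],
                          grid=[0.1, 1.0, 10.0], seed=0)
        assert "s0" in loo.misclassified

    def test_class_size_guard(self, rng):
        X = rng.standard_normal((5, 2))
        y = np.array([1, 0, 0, 0, 0])
        with pytest.raises(ClassificationError):
            loo_predict(X, y, list("abcde"))


class TestTableToXY:
    def test_roundtrip(self, rng):
        table = pd.DataFrame(rng.standard_normal((4, 3)),
                             columns=["f1", "f2", "f3"],
                             index=["a1", "a2", "b1", "b2"])
        table["group"] = [GROUP_A, GROUP_A, GROUP_B, GROUP_B]
        X, y, names, ids = table_to_xy(table)
        assert X.shape == (4, 3)
        assert y.tolist() == [1, 1, 0, 0]
        assert names == ["f1", "f2", "f3"]
        assert ids == ["a1", "a2", "b1", "b2"]

    def test_missing_group_column(self, rng):
        with pytest.raises(ClassificationError):
            table_to_xy(pd.DataFrame(rng.standard_normal((4, 3))))
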