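"""Standardization, correlation filter, RFE, ensemble training, evaluation."""

import numpy as np
import pandas as pd
import pytest

from ctvrecur import model as mdl
from ctvrecur.features import feature_table


def planted_matrix(rng, n=300, p=25, k=5, coefs=(2.0, 1.75, 1.5, 1.25, 1.0)):
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{j}" for j in range(p)])
    beta = np.zeros(p)
    beta[:k] = coefs[:k]
    eta = X.to_numpy() @ beta
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return X, y


class TestStandardize:
    def test_population_sd_convention(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        Z, tr = mdl.standardize(X)
        assert np.allclose(Z["a"], [-1.224745, 0.0, 1.224745], atol=1e-6)

    def test_constant_column_flagged_and_zeroed(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 4.0], "c": [7.0, 7.0, 7.0]})
        Z, tr = mdl.standardize(X)
        assert tr.constant_columns == ("c",)
        assert (Z["c"] == 0).all()

    def test_transform_round_trip(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(2, 3, size=(50, 4)))
        Z, tr = mdl.standardize(X)
        assert np.allclose(tr.transform(X), Z)


class TestCorrelationFilter:
    def test_duplicate_column_dropped_once(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=80)
        X = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=80)})
        kept, log = mdl.correlation_filter(X, threshold=0.95)
        assert sorted(kept) in (["a", "c"], ["b", "c"])
        assert len(log) == 1 and log[0][2] == pytest.approx(1.0)

    def test_orthogonal_columns_untouched(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(200, 6)))
        kept, log = mdl.correlation_filter(X, threshold=0.95)
        assert kept == list(X.columns) and log == []

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(150, 10)),
                         columns=[f"v{j}" for j in range(10)])
        X["v7"] = X["v2"] * 0.995 + rng.normal(scale=0.07, size=150)
        y = (rng.random(150) < 0.5).astype(int)
        kept, log = mdl.correlation_filter(X, y, threshold=0.95)
        # oracle: brute-force scan of every pair
        corr = np.corrcoef(X.to_numpy(), rowvar=False)
        hot = [(i, j) for i in range(10) for j in range(i + 1, 10)
               if abs(corr[i, j]) >= 0.95]
        assert hot, "fixture must contain a planted high-correlation pair"
        dropped = set(X.columns) - set(kept)
        assert len(dropped) == len(hot) == len(log)
        for i, j in hot:
            assert {X.columns[i], X.columns[j]} & dropped

    def test_keeps_feature_more_correlated_with_label(self):
        rng = np.random.default_rng(4)
        y = (rng.random(400) < 0.5).astype(int)
        strong = y + rng.normal(scale=0.5, size=400)
        # same pair-correlation but with part of the label signal removed
        weak = strong - 0.4 * (y - y.mean())
        X = pd.DataFrame({"weak_first": weak, "strong": strong})
        assert abs(np.corrcoef(weak, strong)[0, 1]) > 0.9
        kept, _ = mdl.correlation_filter(X, y, threshold=0.9)
        assert kept == ["strong"]

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            mdl.correlation_filter(pd.DataFrame({"a": [1.0, 2.0]}), threshold=1.5)


class TestRfeCv:
    def test_recovers_planted_features(self):
        hits = 0
        for rep in range(3):
            rng = np.random.default_rng(50 + rep)
            X, y = planted_matrix(rng, n=300, p=25)
            res = mdl.rfe_cv(X, y, folds=4, step=2, seed=rep, n_estimators=60)
            hits += all(f"f{j}" in res.selected for j in range(5))
        assert hits >= 2

    def test_single_big_step_gives_two_subset_sizes(self):
        rng = np.random.default_rng(5)
        X, y = planted_matrix(rng, n=120, p=6, k=2)
        res = mdl.rfe_cv(X, y, folds=3, step=5, seed=0, n_estimators=30)
        assert [s for s, _ in res.rfe_path] == [6, 1]

    def test_deterministic_path(self):
        rng = np.random.default_rng(6)
        X, y = planted_matrix(rng, n=150, p=10, k=3)
        r1 = mdl.rfe_cv(X, y, folds=3, step=2, seed=11, n_estimators=40)
        r2 = mdl.rfe_cv(X, y, folds=3, step=2, seed=11, n_estimators=40)
        assert r1.rfe_path == r2.rfe_path and r1.selected == r2.selected

    def test_single_class_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(30, 4)))
        with pytest.raises(ValueError):
            mdl.rfe_cv(X, np.zeros(30, dtype=int))


class TestTrainModel:
    def test_separable_data_fits_exactly(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(100, 2)), columns=["u", "v"])
        y = (X["u"] > 0).astype(int)
        model, info = mdl.train_model(
            X, y, grid={"max_depth": [None], "n_estimators": [50]}, folds=3
        )
        assert (model.predict(X) == y.to_numpy()).mean() == 1.0

    def test_grid_search_deterministic(self):
        rng = np.random.default_rng(8)
        X, y = planted_matrix(rng, n=200, p=8, k=3)
        grid = {"max_depth": [3, None], "n_estimators": [40, 80]}
        _m1, i1 = mdl.train_model(X, y, grid=grid, folds=3, seed=5)
        _m2, i2 = mdl.train_model(X, y, grid=grid, folds=3, seed=5)
        assert i1 == i2

    def test_probability_averaging_and_vote_agree_mostly(self):
        rng = np.random.default_rng(9)
        X, y = planted_matrix(rng, n=200, p=6, k=3)
        model = mdl.BaggedTreeEnsemble(n_estimators=100, seed=0).fit(X, y)
        score = model.predict_score(X)
        vote = model.predict(X)
        assert ((score >= 0.5).astype(int) == vote).mean() > 0.95

    def test_single_class_rejected(self):
        X = pd.DataFrame(np.zeros((10, 2)))
        with pytest.raises(ValueError):
            mdl.train_model(X, np.ones(10, dtype=int))


class TestSplit:
    def test_cohort_sized_split(self):
        y = np.array([0] * 86 + [1] * 94)
        tr, va = mdl.split_train_validation(range(180), y, 0.8, seed=1)
        assert len(tr) == 144 and len(va) == 36
        assert set(tr) | set(va) == set(range(180))
        assert set(tr) & set(va) == set()
        # stratification preserves the class balance within rounding
        va_pos = sum(1 for i in va if y[i] == 1)
        assert va_pos in (18, 19)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            mdl.split_train_validation(range(10), [0] * 9 + [1], 0.8, seed=0)


class _FixedScore:
    """Stub scorer for metric tests."""

    def __init__(self, scores):
        self.scores = np.asarray(scores, dtype=float)

    def predict_score(self, X):
        return self.scores


class TestEvaluate:
    def test_perfect_separation(self):
        y = [0, 0, 1, 1]
        m = _FixedScore([0.1, 0.2, 0.8, 0.9])
        metrics, roc = mdl.evaluate(m, pd.DataFrame(np.zeros((4, 1))), y)
        assert metrics["auc"] == 1.0 and metrics["accuracy"] == 1.0
        assert metrics["f1"] == 1.0

    def test_auc_equals_concordant_pair_count(self):
        y = np.array([1, 0, 1, 1, 0, 0, 1, 0])
        s = np.array([0.9, 0.8, 0.7, 0.6, 0.55, 0.5, 0.3, 0.1])
        metrics, _ = mdl.evaluate(m := _FixedScore(s), pd.DataFrame(np.zeros((8, 1))), y)
        pos = s[y == 1]; neg = s[y == 0]
        conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert metrics["auc"] == pytest.approx(conc / (len(pos) * len(neg)))

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(10)
        y = (rng.random(60) < 0.5).astype(int)
        y[:2] = [0, 1]
        s = rng.random(60)
        m1, _ = mdl.evaluate(_FixedScore(s), pd.DataFrame(np.zeros((60, 1))), y)
        m2, _ = mdl.evaluate(_FixedScore(np.exp(3 * s)), pd.DataFrame(np.zeros((60, 1))), y)
        assert m1["auc"] == pytest.approx(m2["auc"])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            mdl.evaluate(_FixedScore([0.5, 0.5]), pd.DataFrame(np.zeros((2, 1))), [1, 1])


class TestPipelineHygiene:
    def test_validation_labels_cannot_touch_fitted_quantities(self, cohort64):
        table = feature_table(cohort64)
        y = table["relapse"].astype(int)
        tr_ids, va_ids = mdl.split_train_validation(table.index, y, 0.8, seed=2)
        X = table.drop(columns=["relapse"])

        def fit_stages(y_val):
            yy = y.copy()
            yy.loc[va_ids] = y_val
            Z, sc = mdl.standardize(X.loc[tr_ids])
            kept, _ = mdl.correlation_filter(Z, yy.loc[tr_ids], 0.95)
            kept = [c for c in kept if c not in sc.constant_columns]
            scr = mdl.rfe_cv(Z[kept], yy.loc[tr_ids], folds=3, step=30,
                             seed=2, n_estimators=40)
            model, info = mdl.train_model(
                Z[scr.selected], yy.loc[tr_ids],
                grid={"max_depth": [5], "n_estimators": [50]}, folds=3, seed=2,
            )
            return scr.selected, info, model.predict_score(Z[scr.selected])

        rng = np.random.default_rng(0)
        permuted = y.loc[va_ids].sample(frac=1, random_state=1).to_numpy()
        sel1, info1, score1 = fit_stages(y.loc[va_ids].to_numpy())
        sel2, info2, score2 = fit_stages(permuted)
        assert sel1 == sel2 and info1 == info2
        assert np.array_equal(score1, score2)

    def test_screen_and_train_report_shape(self, cohort64):
        table = feature_table(cohort64)
        report, model, scaler = mdl.screen_and_train(
            table, folds=3, rfe_step=40, seed=4,
            grid={"max_depth": [5], "n_estimators": [50]},
            rfe_n_estimators=40,
        )
        assert report.n_train + report.n_validation == len(table)
        for metrics in (report.metrics_train, report.metrics_validation):
            assert set(metrics) == {"accuracy", "auc", "precision", "recall", "f1"}
            assert all(0 <= v <= 1 for v in metrics.values())
        # ROC points rise monotonically once sorted by threshold
        pts = sorted(report.roc_points, key=lambda p: -p[2])
        fpr = [p[0] for p in pts]; tpr = [p[1] for p in pts]
        assert fpr == sorted(fpr) and tpr == sorted(tpr)
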