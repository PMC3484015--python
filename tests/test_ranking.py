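"""Logistic ranking: fractional-target fit, posterior calibration,
ranked lists, quality scores, ROC and the evaluation protocols."""

import numpy as np
import pandas as pd
import pytest

from nucrank import ranking
from nucrank.ranking import (LogisticModel, dataset_quality, fit_logistic,
                             loso_evaluate, predict_posterior,
                             rank_candidates, roc_area, select_usable,
                             training_size_curve)


def _simulate(seed, n, alpha=-1.0, beta=(2.0, -1.0), fractional=False):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, len(beta))),
                     columns=[f"f{i}" for i in range(len(beta))])
    eta = alpha + X.to_numpy() @ np.asarray(beta)
    p = 1.0 / (1.0 + np.exp(-eta))
    y = p if fractional else (rng.random(n) < p).astype(float)
    return X, pd.Series(y, index=X.index)


class TestFit:
    def test_constant_half_target_gives_flat_posteriors(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(200, 3)),
                         columns=["a", "b", "c"])
        y = np.full(200, 0.5)
        y[0] = 0.5  # keep two distinct values requirement honest below
        with pytest.raises(ValueError):
            fit_logistic(X, y)
        y[:100] = 0.5 - 1e-12  # numerically identical mean target
        y2 = np.concatenate([np.full(100, 0.0), np.full(100, 1.0)])
        X2 = pd.concat([X.iloc[:100], X.iloc[:100]], ignore_index=True)
        model = fit_logistic(X2, y2)  # same features, labels average 0.5
        post = predict_posterior(model, X2)
        assert np.allclose(post, 0.5, atol=0.02)
        assert abs(model.intercept) < 0.05
        assert all(abs(v) < 0.05 for v in model.coefficients.values())

    def test_parameter_recovery(self):
        X, y = _simulate(0, 5000)
        model = fit_logistic(X, y, lambda_=1e-4)
        alpha, raw = model.raw_coefficients()
        assert alpha == pytest.approx(-1.0, rel=0.10)
        assert raw["f0"] == pytest.approx(2.0, rel=0.10)
        assert raw["f1"] == pytest.approx(-1.0, rel=0.10)

    def test_duplicating_rows_leaves_model_unchanged(self):
        X, y = _simulate(1, 400)
        m1 = fit_logistic(X, y)
        m2 = fit_logistic(pd.concat([X, X], ignore_index=True),
                          pd.concat([y, y], ignore_index=True))
        assert m1.intercept == pytest.approx(m2.intercept, abs=1e-5)
        for f in m1.feature_names:
            assert m1.coefficients[f] == pytest.approx(
                m2.coefficients[f], abs=1e-5)

    def test_separable_without_ridge_raises(self):
        X = pd.DataFrame({"f": np.concatenate([np.full(50, -1.0),
                                               np.full(50, 1.0)])
                          + np.random.default_rng(0).normal(0, 0.01, 100)})
        y = (X["f"] > 0).astype(float)
        with pytest.raises(RuntimeError, match="lambda"):
            fit_logistic(X, y, lambda_=0.0)

    def test_constant_feature_dropped(self):
        X, y = _simulate(2, 300)
        X["const"] = 3.0
        model = fit_logistic(X, y)
        assert "const" not in model.feature_names

    def test_model_json_round_trip(self):
        X, y = _simulate(3, 300)
        m = fit_logistic(X, y)
        m2 = LogisticModel.from_json(m.to_json())
        assert np.allclose(predict_posterior(m, X),
                           predict_posterior(m2, X))


class TestPredict:
    def _null_model(self):
        return LogisticModel(intercept=0.0, coefficients={"f": 0.0},
                             means={"f": 0.0}, scales={"f": 1.0},
                             feature_names=["f"], lambda_=0.0)

    def test_zero_model_gives_half(self):
        X = pd.DataFrame({"f": [-5.0, 0.0, 7.0]})
        assert np.allclose(predict_posterior(self._null_model(), X), 0.5)

    def test_log3_predictor_gives_three_quarters(self):
        m = self._null_model()
        m.intercept = np.log(3.0)
        assert predict_posterior(m, pd.DataFrame({"f": [0.0]}))[0] == \
            pytest.approx(0.75)

    def test_monotone_in_positive_coefficient(self):
        m = self._null_model()
        m.coefficients["f"] = 1.5
        X = pd.DataFrame({"f": np.linspace(-3, 3, 50)})
        p = predict_posterior(m, X).to_numpy()
        assert np.all(np.diff(p) > 0)

    def test_missing_column_named(self):
        with pytest.raises(ValueError, match="f"):
            predict_posterior(self._null_model(),
                              pd.DataFrame({"g": [1.0]}))


class TestRank:
    def test_basic_order(self):
        ranked = rank_candidates(pd.Series([0.2, 0.9, 0.5],
                                           index=["a", "b", "c"]))
        assert list(ranked["object_id"]) == ["b", "c", "a"]
        assert list(ranked["rank"]) == [1, 2, 3]

    def test_ties_broken_by_object_id(self):
        ranked = rank_candidates(pd.Series([0.5, 0.5, 0.5],
                                           index=["c", "a", "b"]))
        assert list(ranked["object_id"]) == ["a", "b", "c"]

    def test_against_sort_oracle(self):
        rng = np.random.default_rng(0)
        p = pd.Series(rng.random(1000),
                      index=[f"o{i:04d}" for i in range(1000)])
        ranked = rank_candidates(p)
        oracle = sorted(p.items(), key=lambda kv: (-kv[1], kv[0]))
        assert list(ranked["object_id"]) == [k for k, _ in oracle]
        assert (ranked["posterior"].diff().dropna() <= 0).all()


class TestQuality:
    def test_examples(self):
        assert dataset_quality([1, 1, 1]).value == 1.0
        assert dataset_quality([0.2, 0.4, 0.6, 0.8]).value == \
            pytest.approx(0.5)

    def test_equals_area_under_sorted_curve(self):
        rng = np.random.default_rng(4)
        p = rng.random(100)
        q = dataset_quality(p)
        # discrete-sum oracle: area under the sorted step curve with
        # domain normalised to [0, 1]
        area = np.sort(p).sum() / p.size
        assert q.value == pytest.approx(area)
        assert q.value == pytest.approx(p.sum() / p.size)

    def test_ordering_invariance(self):
        rng = np.random.default_rng(5)
        p = rng.random(50)
        assert dataset_quality(p).value == \
            dataset_quality(p[::-1]).value == \
            dataset_quality(rng.permutation(p)).value

    def test_empty_scope_raises(self):
        with pytest.raises(ValueError):
            dataset_quality([])


class TestRoc:
    def test_perfect_separation(self):
        assert roc_area([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores(self):
        assert roc_area([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_six_point_toy_vs_pair_counting_oracle(self):
        scores = [0.9, 0.8, 0.8, 0.4, 0.3, 0.1]
        labels = [1.0, 0.0, 1.0, 1.0, 0.0, 0.0]
        pos = [s for s, l in zip(scores, labels) if l >= 0.5]
        neg = [s for s, l in zip(scores, labels) if l < 0.5]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        oracle = wins / (len(pos) * len(neg))
        assert roc_area(scores, labels) == pytest.approx(oracle)

    def test_complement_identity(self):
        rng = np.random.default_rng(6)
        s = rng.normal(size=40)  # continuous: no ties
        y = rng.integers(0, 2, 40).astype(float)
        y[0], y[1] = 0, 1
        assert roc_area(s, y) + roc_area(-s, y) == pytest.approx(1.0)

    def test_cross_check_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(7)
        s = rng.normal(size=200)
        y = (rng.random(200) < 0.4).astype(float)
        assert roc_area(s, y) == pytest.approx(
            roc_auc_score(y >= 0.5, s))

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_area([0.1, 0.9], [1, 1])


def _clustered_dataset(seed=0, n_per=50):
    """Two subjects x two cores with linearly separable classes."""
    rng = np.random.default_rng(seed)
    rows, subj, core, ys = [], [], [], []
    for s in ("S01", "S02"):
        for c in ("a", "b"):
            for i in range(n_per):
                good = i % 2 == 0
                mu = 2.0 if good else -2.0
                rows.append(rng.normal(mu, 0.3, 3))
                subj.append(s)
                core.append(f"{s}{c}")
                ys.append(1.0 if good else 0.0)
    idx = [f"o{i}" for i in range(len(rows))]
    X = pd.DataFrame(rows, columns=["f0", "f1", "f2"], index=idx)
    return (X, pd.Series(ys, index=idx), pd.Series(subj, index=idx),
            pd.Series(core, index=idx))


class TestLoso:
    def test_separable_folds_are_perfect(self):
        X, y, subj, core = _clustered_dataset()
        folds, summary = loso_evaluate(X, y, subj, core)
        assert summary["n_folds"] == 4
        assert all(f.roc == 1.0 for f in folds)

    def test_fold_count_equals_core_count(self):
        X, y, subj, core = _clustered_dataset()
        folds, _ = loso_evaluate(X, y, subj, core)
        assert {f.held_out for f in folds} == set(core.unique())

    def test_no_leakage_from_held_out_labels(self):
        X, y, subj, core = _clustered_dataset()
        y2 = y.copy()
        y2[subj == "S02"] = 1.0 - y2[subj == "S02"]  # scramble held-out
        m1 = ranking.fit_logistic(X[subj != "S02"], y[subj != "S02"])
        m2 = ranking.fit_logistic(X[subj != "S02"], y2[subj != "S02"])
        assert m1.coefficients == m2.coefficients

    def test_training_order_invariance(self):
        X, y, subj, core = _clustered_dataset()
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(X))
        folds_a, _ = loso_evaluate(X, y, subj, core)
        folds_b, _ = loso_evaluate(X.iloc[perm], y.iloc[perm],
                                   subj.iloc[perm], core.iloc[perm])
        assert [f.roc for f in folds_a] == [f.roc for f in folds_b]


class TestTrainingSize:
    def test_one_row_per_size(self):
        X, y, *_ = _clustered_dataset(n_per=40)
        curve = training_size_curve(X, y, sizes=(8, 16, 32), reps=3,
                                    seed=0)
        assert list(curve["size"]) == [8, 16, 32]

    def test_single_rep_matches_direct_run(self):
        X, y, *_ = _clustered_dataset(n_per=40)
        curve = training_size_curve(X, y, sizes=(16,), reps=1, seed=3)
        rng = np.random.default_rng(3)
        idx = rng.choice(len(X), size=16, replace=False)
        mask = np.zeros(len(X), bool)
        mask[idx] = True
        model = ranking.fit_logistic(X.iloc[idx], y.iloc[idx])
        post = predict_posterior(model, X.iloc[~mask])
        expect = roc_area(post.to_numpy(), y.iloc[~mask].to_numpy())
        assert curve["roc_mean"][0] == pytest.approx(expect)

    def test_variance_shrinks_with_training_size(self):
        rng = np.random.default_rng(9)
        n = 700
        X = pd.DataFrame(rng.normal(size=(n, 3)),
                         columns=["f0", "f1", "f2"])
        eta = X["f0"] * 1.5 - X["f1"]
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-eta)))
                      .astype(float), index=X.index)
        curve = training_size_curve(X, y, sizes=(8, 512), reps=60, seed=2)
        v = curve.set_index("size")["roc_var"]
        assert v[512] < v[8]


class TestSelect:
    def _ranked(self, p):
        return rank_candidates(pd.Series(p, index=[f"o{i}"
                                                   for i in range(len(p))]))

    def test_threshold_screen(self):
        sel = select_usable(self._ranked([0.05, 0.15, 0.95]),
                            ("threshold", 0.1))
        assert sorted(sel) == ["o1", "o2"]

    def test_top_one_is_argmax(self):
        sel = select_usable(self._ranked([0.2, 0.8, 0.5]), ("top_n", 1))
        assert sel == ["o1"]

    def test_top_n_overflow_returns_all(self):
        sel = select_usable(self._ranked([0.2, 0.8]), ("top_n", 10))
        assert len(sel) == 2

    def test_weight_passthrough_total_is_quality_identity(self):
        p = [0.2, 0.4, 0.6]
        ranked = self._ranked(p)
        sel = select_usable(ranked, ("weights",))
        assert len(sel) == 3
        total = ranked.set_index("object_id").loc[sel, "posterior"].sum()
        q = dataset_quality(p)
        assert total == pytest.approx(q.value * q.n)
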