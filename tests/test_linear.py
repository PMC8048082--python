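import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mtqsarx import boxjenkins as bj
from mtqsarx import linear as lm
from mtqsarx.dataset import SyntheticSpec, generate_synthetic

from .conftest import make_dataset


def planted_features(n=120, n_noise=6, sep=3.0, seed=0):
    """One strongly informative column among pure-noise columns."""
    rng = np.random.default_rng(seed)
    y = np.array([1, -1] * (n // 2))
    signal = np.where(y == 1, sep, -sep) + rng.normal(0, 1.0, n)
    data = {"signal": signal}
    for k in range(n_noise):
        data[f"noise{k}"] = rng.normal(0, 1.0, n)
    return pd.DataFrame(data), y


class TestPretreat:
    def test_constant_column_removed(self):
        X = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1, 2, 3, 4.0]})
        reduced, rep = lm.pretreat(X, variance_cutoff=0.001, correlation_cutoff=1.0)
        assert list(reduced.columns) == ["b"]
        assert rep.removed_constant == ["a"]

    def test_duplicated_column_cutoff_one(self):
        X = pd.DataFrame({"a": [1, 2, 3, 4.0], "b": [1, 2, 3, 4.0]})
        reduced, rep = lm.pretreat(X, 0.0, 1.0)
        assert list(reduced.columns) == ["a"]
        assert rep.removed_correlated[0][:2] == ("a", "b")

    def test_correlation_threshold_behaviour(self):
        # construct two columns with known |r| = 0.96
        rng = np.random.default_rng(1)
        n = 2000
        a = rng.normal(size=n)
        rho = 0.96
        b = rho * a + np.sqrt(1 - rho ** 2) * rng.normal(size=n)
        # rescale b so the empirical correlation is exactly 0.96 by regression
        r = np.corrcoef(a, b)[0, 1]
        X = pd.DataFrame({"a": a, "b": b})
        reduced_hi, _ = lm.pretreat(X, 0.0, 0.999)
        assert list(reduced_hi.columns) == ["a", "b"]
        reduced_lo, rep = lm.pretreat(X, 0.0, min(abs(r), 0.95))
        assert list(reduced_lo.columns) == ["a"]

    def test_survivors_satisfy_invariant(self, synthetic_ds):
        model = bj.fit_boxjenkins(synthetic_ds, 1)
        X = bj.transform(synthetic_ds, model).X
        reduced, rep = lm.pretreat(X, 0.001, 0.9)
        corr = reduced.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() < 0.9

    def test_all_removed_errors(self):
        X = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        with pytest.raises(ValueError):
            lm.pretreat(X, 0.001, 1.0)


class TestWilksLambda:
    def test_no_discrimination_limit(self):
        lam, f, p = lm.wilks_lambda([1, 2, 1, 2], [1, 1, -1, -1])
        assert lam == pytest.approx(1.0)

    def test_perfect_discrimination_limit(self):
        lam, f, p = lm.wilks_lambda([1, 1, 2, 2], [1, 1, -1, -1])
        assert lam == pytest.approx(0.0)
        assert p == pytest.approx(0.0)

    def test_hand_variance_decomposition(self):
        """Brute-force SSwithin/SStotal oracle on {1,2} vs {3,4}."""
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([1, 1, -1, -1])
        grand = scores.mean()
        ss_total = ((scores - grand) ** 2).sum()
        ss_within = sum(((scores[labels == g] - scores[labels == g].mean()) ** 2).sum()
                        for g in (1, -1))
        lam, f, p = lm.wilks_lambda(scores, labels)
        assert lam == pytest.approx(ss_within / ss_total)
        assert lam == pytest.approx(0.2)
        # F from the one-way identity, p from the F distribution
        assert f == pytest.approx(((ss_total - ss_within) / 1) / (ss_within / 2))
        assert p == pytest.approx(stats.f.sf(f, 1, 2))

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            lm.wilks_lambda([1, 2, 3], [1, 1, 1])


class TestFsLda:
    def test_planted_signal_selected_first(self):
        X, y = planted_features(seed=3)
        model = lm.fs_lda(X, y, 0.05, 0.05, 5)
        assert model.selection_log[0]["descriptor"] == "signal"
        assert model.wilks_lambda < 0.5

    def test_null_features_no_model(self):
        """All-noise features yield a no-model error in >= 90% of 20 seeds.

        The candidate count is kept small: entry tests no multiplicity
        correction, so P(no model) = 0.95^m under the null and the 90%
        bound only holds for m <= 2.
        """
        failures = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(60, 2)),
                             columns=[f"n{k}" for k in range(2)])
            y = np.array([1, -1] * 30)
            try:
                lm.fs_lda(X, y, 0.05, 0.05, 5)
            except ValueError:
                failures += 1
        assert failures >= 18

    def test_selection_log_entries_below_p_enter(self):
        X, y = planted_features(n=200, n_noise=10, seed=5)
        model = lm.fs_lda(X, y, 0.05, 0.05, 10)
        entries = [e for e in model.selection_log if e["action"] == "enter"]
        assert [e["step"] for e in model.selection_log] == \
            list(range(1, len(model.selection_log) + 1))
        assert all(e["p_value"] < 0.05 for e in entries)

    def test_max_descriptors_respected(self):
        X, y = planted_features(n=200, n_noise=10, seed=6)
        model = lm.fs_lda(X, y, 0.5, 0.5, 2)
        assert len(model.selected) <= 2

    def test_determinism(self):
        X, y = planted_features(seed=9)
        a = lm.fs_lda(X, y, 0.05, 0.05, 5)
        b = lm.fs_lda(X, y, 0.05, 0.05, 5)
        assert a.selected == b.selected
        assert a.wilks_lambda == b.wilks_lambda


class TestSfsLda:
    def test_planted_signal_selected(self):
        X, y = planted_features(seed=2)
        model = lm.sfs_lda(X, y, "accuracy", True, 3, 5, seed=0)
        assert "signal" in model.selected
        majority = max((y == 1).mean(), (y == -1).mean())
        assert model.selection_log[0]["score"] > majority

    def test_max_one_matches_univariate_oracle(self):
        X, y = planted_features(n=100, n_noise=5, sep=1.0, seed=4)
        model = lm.sfs_lda(X, y, "accuracy", False, 1, 5, seed=1)
        assert len(model.selected) == 1
        # exhaustive univariate oracle with the same CV machinery
        scores = {c: lm._cv_score(X, y, [c], "accuracy", 5, 1) for c in X.columns}
        best = max(scores.values())
        assert scores[model.selected[0]] == pytest.approx(best)

    def test_determinism_both_scorings(self):
        X, y = planted_features(seed=8)
        for scoring in ("accuracy", "auroc"):
            a = lm.sfs_lda(X, y, scoring, True, 3, 5, seed=5)
            b = lm.sfs_lda(X, y, scoring, True, 3, 5, seed=5)
            assert a.selected == b.selected

    def test_cv_folds_exceeding_class_count_errors(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4, 5, 6]})
        y = np.array([1, 1, 1, 1, 1, -1])
        with pytest.raises(ValueError):
            lm.sfs_lda(X, y, "accuracy", False, 1, 5, seed=0)


class TestCrossCorrelation:
    def test_duplicated_pair(self):
        X = pd.DataFrame({"a": [1, 2, 3, 4.0], "b": [2, 4, 6, 8.0]})
        corr, max_off = lm.cross_correlation(X)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert max_off == pytest.approx(1.0)

    def test_orthogonal_pair(self):
        X = pd.DataFrame({"a": [1, -1, 1, -1.0], "b": [1, 1, -1, -1.0]})
        corr, max_off = lm.cross_correlation(X)
        assert abs(corr.loc["a", "b"]) < 1e-10

    def test_three_feature_brute_force(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        corr, _ = lm.cross_correlation(X)
        for i in "abc":
            for j in "abc":
                x, z = X[i].to_numpy(), X[j].to_numpy()
                r = (((x - x.mean()) * (z - z.mean())).sum()
                     / np.sqrt(((x - x.mean()) ** 2).sum() * ((z - z.mean()) ** 2).sum()))
                assert corr.loc[i, j] == pytest.approx(r)

    def test_constant_feature_reported_nan(self):
        X = pd.DataFrame({"a": [1, 2, 3.0], "k": [5, 5, 5.0]})
        corr, _ = lm.cross_correlation(X)
        assert np.isnan(corr.loc["a", "k"])


def _fit_on_synthetic(ds, seed=0):
    model_bj = bj.fit_boxjenkins(ds, 1)
    X = bj.transform(ds, model_bj).X
    y = ds.response.to_numpy()
    return lm.fs_lda(X, y, 0.05, 0.05, 6), X, y


class TestYcRandomize:
    def test_strong_signal_randomisation_degrades(self):
        ds = generate_synthetic(SyntheticSpec(
            n_rows=240, n_descriptors=4, condition_cardinalities=(3, 2),
            active_fraction=0.6, effect_size=2.5, noise_sd=0.8, seed=13))
        model, X, y = _fit_on_synthetic(ds)
        assert model.wilks_lambda <= 0.5
        rep = lm.yc_randomize(ds, model, 1, n_runs=30, seed=1)
        assert rep.lambda_r >= 0.9
        assert rep.lambda_r > model.wilks_lambda

    def test_single_run_determinism(self, synthetic_ds):
        model, _, _ = _fit_on_synthetic(synthetic_ds)
        a = lm.yc_randomize(synthetic_ds, model, 1, n_runs=1, seed=42)
        b = lm.yc_randomize(synthetic_ds, model, 1, n_runs=1, seed=42)
        pd.testing.assert_frame_equal(a.runs, b.runs)
        assert a.lambda_r == b.lambda_r

    def test_noise_fixture_lambda_near_one_both(self):
        ds = generate_synthetic(SyntheticSpec(
            n_rows=300, n_descriptors=4, condition_cardinalities=(2, 2),
            active_fraction=0.5, effect_size=0.0, noise_sd=1.0, seed=17))
        model_bj = bj.fit_boxjenkins(ds, 1)
        X = bj.transform(ds, model_bj).X
        y = ds.response.to_numpy()
        # force a model on noise by relaxing the entry threshold
        model = lm.fs_lda(X, y, p_enter=1.0, p_remove=1.0, max_descriptors=3)
        rep = lm.yc_randomize(ds, model, 1, n_runs=30, seed=2)
        assert abs(rep.lambda_r - model.wilks_lambda) < 0.1
        assert rep.lambda_r > 0.9

    def test_report_table_consistency(self, synthetic_ds):
        model, _, _ = _fit_on_synthetic(synthetic_ds)
        rep = lm.yc_randomize(synthetic_ds, model, 1, n_runs=5, seed=3)
        assert len(rep.runs) == 5
        assert rep.lambda_r == pytest.approx(rep.runs["wilks_lambda"].mean())
        assert rep.accuracy_r == pytest.approx(rep.runs["accuracy_pct"].mean())

    def test_unreconstructible_descriptor_errors(self, synthetic_ds):
        model, _, _ = _fit_on_synthetic(synthetic_ds)
        model.selected = ["d(NOPE)::c1"]
        with pytest.raises(ValueError, match="NOPE"):
            lm.yc_randomize(synthetic_ds, model, 1, n_runs=1, seed=0)


class TestLambdaMonotonicity:
    def test_lambda_weakly_decreases_with_informative_descriptor(self):
        X, y = planted_features(n=150, n_noise=4, sep=1.5, seed=31)
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        lam = []
        for cols in (["noise0"], ["noise0", "signal"]):
            lda = LinearDiscriminantAnalysis().fit(X[cols], y)
            lam.append(lm.wilks_lambda(lda.decision_function(X[cols]), y)[0])
        assert lam[1] <= lam[0]
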