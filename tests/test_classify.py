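"""Lasso logit, jackknife, curves, permutation control and gates."""

import numpy as np
import pytest

from necrogeo.classify import (
    JackknifeRecord,
    _lambda_max,
    accuracy_curve,
    depth_gate,
    fit_lasso_logit,
    jackknife,
    permutation_control,
    predict_prob,
    roc_curve,
)
from necrogeo.embed import embed
from necrogeo.sketch import SimilarityMatrix


def standardize(X):
    return (X - X.mean(0)) / X.std(0)


class TestLassoFit:
    def test_lambda_max_gives_prior_only_model(self, logit_fixture):
        X, y, labels = logit_fixture
        lam_max = _lambda_max(standardize(X), y)
        model = fit_lasso_logit(X, labels, lambda_grid=[lam_max * 1.001])
        assert np.all(model.coef == 0.0)
        prior = np.log(y.mean() / (1 - y.mean()))
        assert model.intercept == pytest.approx(prior, abs=1e-8)
        assert model.prior_only

    def test_unpenalized_matches_newton_mle_oracle(self, logit_fixture):
        import statsmodels.api as sm

        X, y, labels = logit_fixture
        model = fit_lasso_logit(X, labels, lambda_grid=[0.0])
        oracle = sm.Logit(y, sm.add_constant(standardize(X))).fit(
            disp=0, method="newton", tol=1e-12
        )
        params = np.asarray(oracle.params)
        assert model.intercept == pytest.approx(params[0], abs=1e-6)
        assert np.allclose(model.coef, params[1:], atol=1e-6)

    def test_agrees_with_sklearn_saga_at_fixed_penalty(self, logit_fixture):
        """Dual-route check: our CD solver vs sklearn's saga on one lambda."""
        from sklearn.linear_model import LogisticRegression

        X, y, labels = logit_fixture
        Xs = standardize(X)
        lam = 0.02
        model = fit_lasso_logit(Xs, labels, lambda_grid=[lam])
        clf = LogisticRegression(
            l1_ratio=1.0, solver="saga", C=1.0 / (len(y) * lam), tol=1e-10, max_iter=200_000
        )
        clf.fit(Xs, y)
        assert model.intercept == pytest.approx(float(clf.intercept_[0]), abs=1e-4)
        assert np.allclose(model.coef, clf.coef_[0], atol=1e-4)

    def test_separating_dimension_selected(self, rng):
        X = rng.standard_normal((30, 5))
        X[:15, 2] += 4.0
        labels = ["a"] * 15 + ["b"] * 15
        model = fit_lasso_logit(X, labels, seed=0)
        assert model.coef[2] != 0.0
        preds = predict_prob(model, X) > 0.5
        truth = np.array([lbl == "b" for lbl in labels])
        assert np.array_equal(preds, truth)

    def test_path_sparsity_monotone_in_lambda(self, logit_fixture):
        X, _, labels = logit_fixture
        Xs = standardize(X)
        lam_max = _lambda_max(Xs, np.array([1.0 if l == "pos" else 0.0 for l in labels]))
        grid = np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-3), 30)
        nnz = [
            fit_lasso_logit(X, labels, lambda_grid=[lam]).n_nonzero for lam in grid
        ]
        assert all(a <= b for a, b in zip(nnz, nnz[1:]))

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError, match="2 classes"):
            fit_lasso_logit(X, ["a"] * 10)

    def test_zero_variance_dimension_dropped(self, logit_fixture):
        X, _, labels = logit_fixture
        X2 = np.column_stack([X, np.full(len(labels), 3.14)])
        model = fit_lasso_logit(X2, labels, lambda_grid=[0.01])
        assert 3 not in model.kept_dims.tolist()
        assert predict_prob(model, X2[0]) == pytest.approx(
            predict_prob(fit_lasso_logit(X, labels, lambda_grid=[0.01]), X[0]), abs=1e-8
        )


class TestPredictProb:
    def _null_model(self, intercept, logit_fixture):
        X, _, labels = logit_fixture
        model = fit_lasso_logit(X, labels, lambda_grid=[10.0])
        model.intercept = intercept
        model.coef = np.zeros_like(model.coef)
        return model, X

    def test_zero_model_gives_half(self, logit_fixture):
        model, X = self._null_model(0.0, logit_fixture)
        assert predict_prob(model, X[0]) == pytest.approx(0.5)

    def test_log3_intercept_gives_three_quarters(self, logit_fixture):
        model, X = self._null_model(np.log(3.0), logit_fixture)
        assert predict_prob(model, X[0]) == pytest.approx(0.75)

    def test_dimension_mismatch_rejected(self, logit_fixture):
        X, _, labels = logit_fixture
        model = fit_lasso_logit(X, labels, lambda_grid=[0.1])
        with pytest.raises(ValueError, match="coordinates"):
            predict_prob(model, np.zeros(7))


def _two_cluster_similarity(rng, n_per=8, gap=0.5, noise=0.02):
    n = 2 * n_per
    labels = ["a"] * n_per + ["b"] * n_per
    base = np.full((n, n), 0.4)
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                base[i, j] += gap
    base += rng.normal(0, noise, (n, n))
    S = (base + base.T) / 2
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix([f"s{i}" for i in range(n)], S), labels


class TestJackknife:
    def test_one_record_per_sample_and_separated_data_all_correct(self, rng):
        S, labels = _two_cluster_similarity(rng)
        records = jackknife(S, labels, seed=0)
        assert len(records) == len(S.sample_ids)
        assert [r.sample_id for r in records] == S.sample_ids
        assert all(r.correct for r in records)

    def test_label_mapping_interface(self, rng):
        S, labels = _two_cluster_similarity(rng)
        by_id = dict(zip(S.sample_ids, labels))
        a = jackknife(S, labels, seed=1)
        b = jackknife(S, by_id, seed=1)
        assert [(r.sample_id, r.p_true) for r in a] == [(r.sample_id, r.p_true) for r in b]

    def test_too_few_samples_rejected(self, rng):
        S, labels = _two_cluster_similarity(rng, n_per=2)
        with pytest.raises(ValueError):
            jackknife(S, labels)

    def test_re_embed_mode_also_separates(self, rng):
        S, labels = _two_cluster_similarity(rng)
        records = jackknife(S, labels, seed=0, re_embed_per_fold=True)
        assert sum(r.correct for r in records) >= 14  # 16 samples


class TestAccuracyCurve:
    def test_hand_counted_values(self):
        records = [
            JackknifeRecord("a", "x", 0.9, "x", p_positive=0.9),
            JackknifeRecord("b", "x", 0.6, "x", p_positive=0.6),
            JackknifeRecord("c", "y", 0.4, "x", p_positive=0.6),  # wrong
        ]
        curve = accuracy_curve(records, thresholds=[0.5, 0.8])
        assert curve.values[0] == pytest.approx(2 / 3)
        assert curve.values[1] == pytest.approx(1 / 3)

    def test_certain_records_give_constant_one(self):
        records = [
            JackknifeRecord(f"s{i}", "x", 1.0, "x", p_positive=1.0) for i in range(4)
        ]
        curve = accuracy_curve(records)
        assert np.all(curve.values == 1.0)

    def test_non_increasing_for_random_records(self, rng):
        records = [
            JackknifeRecord(
                f"s{i}",
                "x",
                float(p),
                "x" if ok else "y",
                p_positive=float(p),
            )
            for i, (p, ok) in enumerate(zip(rng.random(50), rng.random(50) > 0.3))
        ]
        curve = accuracy_curve(records)
        assert np.all(np.diff(curve.values) <= 0)


class TestRoc:
    def _records(self, probs, truths):
        return [
            JackknifeRecord(f"s{i}", t, p if t == "pos" else 1 - p, None, p_positive=p)
            for i, (p, t) in enumerate(zip(probs, truths))
        ]

    def test_perfect_separation_auc_one(self):
        r = self._records([0.9, 0.8, 0.3, 0.2], ["pos", "pos", "neg", "neg"])
        assert roc_curve(r).auc == pytest.approx(1.0)

    def test_swapped_middle_labels_auc_by_pair_enumeration(self):
        # pos scores {0.9, 0.3} vs neg {0.8, 0.2}: 3 of 4 pairs ordered
        r = self._records([0.9, 0.8, 0.3, 0.2], ["pos", "neg", "pos", "neg"])
        assert roc_curve(r).auc == pytest.approx(0.75)

    def test_constant_probabilities_auc_half(self):
        r = self._records([0.6] * 6, ["pos", "neg"] * 3)
        assert roc_curve(r).auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        r = self._records([0.6, 0.7], ["pos", "pos"])
        with pytest.raises(ValueError):
            roc_curve(r)


class TestPermutationControl:
    def test_group_sizes_balanced_and_seeded(self, rng):
        S, labels = _two_cluster_similarity(rng)
        a = permutation_control(S, labels, seed=5)
        b = permutation_control(S, labels, seed=5)
        assert a.permuted_labels == b.permuted_labels
        counts = {v: a.permuted_labels.count(v) for v in set(a.permuted_labels)}
        assert abs(counts["mock_A"] - counts["mock_B"]) <= 1


class TestDepthGate:
    def test_million_read_boundary(self):
        counts = {"low": 999_999, "exact": 1_000_000, "high": 2_000_000}
        included, excluded = depth_gate(counts)
        assert excluded == ["low"]
        assert set(included) == {"exact", "high"}

    def test_no_exclusions_when_all_pass(self):
        included, excluded = depth_gate({"a": 10, "b": 20}, min_reads=5)
        assert excluded == []
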