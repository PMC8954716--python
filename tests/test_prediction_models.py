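"""Logistic prediction models and ROC analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import logit

from pps import prediction_models as pm
from pps.prediction_models import ModelSpec


def auc_bruteforce(scores, labels):
    """Pairwise concordance over every (case, control) pair; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocCurve:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ((1, 2, 3, 4), (0, 0, 1, 1), 1.0),
            ((1, 3, 2, 4), (0, 0, 1, 1), 0.75),
            ((4, 3, 2, 1), (0, 0, 1, 1), 0.0),
            ((1, 1, 1, 1), (0, 0, 1, 1), 0.5),  # all tied
        ],
    )
    def test_small_examples_against_pair_counting(self, scores, labels, expected):
        labels = np.array(labels, dtype=bool)
        res = pm.roc_curve(scores, labels)
        assert res.auc == pytest.approx(expected, abs=1e-12)
        assert res.auc == pytest.approx(auc_bruteforce(scores, labels), abs=1e-12)

    @given(
        st.lists(st.integers(0, 5), min_size=4, max_size=40).filter(
            lambda s: len(s) >= 4
        ),
        st.integers(0, 2**31 - 1),
    )
    def test_concordance_equals_bruteforce_with_ties(self, score_ints, seed):
        rng = np.random.default_rng(seed)
        labels = np.zeros(len(score_ints), dtype=bool)
        labels[rng.choice(len(score_ints), size=len(score_ints) // 2, replace=False)] = True
        if labels.all() or not labels.any():
            return
        scores = np.array(score_ints, dtype=float)  # small ints force ties
        res = pm.roc_curve(scores, labels)
        assert res.auc == pytest.approx(auc_bruteforce(scores, labels), abs=1e-12)

    def test_matches_reference_implementation(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        scores = rng.normal(size=500) + np.repeat([0.0, 0.8], 250)
        labels = np.repeat([False, True], 250)
        assert pm.roc_curve(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_auc_equals_trapezoidal_area_under_empirical_curve(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=300)
        labels = rng.random(300) < 0.4
        res = pm.roc_curve(scores, labels)
        assert res.auc == pytest.approx(np.trapezoid(res.tpr, res.fpr), abs=1e-12)

    @pytest.mark.parametrize(
        "transform", [lambda s: 2 * s + 7, np.exp, lambda s: s**3]
    )
    def test_auc_invariant_under_increasing_transforms(self, transform):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=200)
        labels = rng.random(200) < 0.5
        base = pm.roc_curve(scores, labels).auc
        assert pm.roc_curve(transform(scores), labels).auc == pytest.approx(base, abs=1e-12)

    def test_uninformative_scores_give_null_auc(self):
        rng = np.random.default_rng(17)
        scores = rng.normal(size=10_000)
        labels = rng.random(10_000) < 0.5
        assert pm.roc_curve(scores, labels).auc == pytest.approx(0.5, abs=0.02)

    def test_one_class_absent_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            pm.roc_curve([1.0, 2.0], [True, True])

    def test_binary_exposure_auc_is_mean_of_sensitivity_specificity(self):
        # two-point ROC: AUC = (se + sp) / 2 of the binary exposure itself
        rng = np.random.default_rng(23)
        exposure = rng.random(2000) < 0.45
        labels = rng.random(2000) < np.where(exposure, 0.7, 0.45)
        res = pm.roc_curve(exposure.astype(float), labels)
        se = (exposure & labels).sum() / labels.sum()
        sp = (~exposure & ~labels).sum() / (~labels).sum()
        assert res.auc == pytest.approx((se + sp) / 2, abs=1e-12)

    def test_youden_point_and_interval_invariants(self):
        rng = np.random.default_rng(31)
        scores = rng.normal(size=400) + np.repeat([0.0, 1.0], 200)
        labels = np.repeat([False, True], 200)
        res = pm.roc_curve(scores, labels)
        assert res.auc_ci_low <= res.auc <= res.auc_ci_high
        assert 0 <= res.sensitivity <= 100 and 0 <= res.specificity <= 100
        assert res.sensitivity_ci[0] <= res.sensitivity <= res.sensitivity_ci[1]
        assert res.specificity_ci[0] <= res.specificity <= res.specificity_ci[1]
        # the reported threshold actually attains the reported operating point
        pred = scores >= res.threshold
        assert 100 * (pred & labels).sum() / labels.sum() == pytest.approx(res.sensitivity)


class TestFitLogistic:
    def test_null_model_intercept_is_logit_of_prevalence(self):
        y = np.zeros(85, dtype=bool)
        y[:53] = True  # prevalence 62.4%
        cohort = pd.DataFrame({"outcome": y})
        fitted = pm.fit_logistic(cohort, ModelSpec("null", "outcome", ()))
        assert fitted.coefficients["intercept"] == pytest.approx(logit(53 / 85), abs=1e-6)

    def test_perfect_separation_flagged(self):
        cohort = pd.DataFrame({"x": [0, 0, 0, 1, 1, 1], "outcome": [False] * 3 + [True] * 3})
        with pytest.warns(UserWarning, match="separation"):
            fitted = pm.fit_logistic(cohort, ModelSpec("sep", "outcome", ("x",)))
        assert fitted.separated

    def test_parameter_recovery_on_simulated_data(self):
        rng = np.random.default_rng(41)
        n = 5000
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-1.0 + 1.1 * x)))
        cohort = pd.DataFrame({"x": x, "outcome": rng.random(n) < p})
        fitted = pm.fit_logistic(cohort, ModelSpec("sim", "outcome", ("x",)))
        assert fitted.converged and not fitted.separated
        assert fitted.coefficients["intercept"] == pytest.approx(-1.0, abs=0.15)
        assert fitted.coefficients["x"] == pytest.approx(1.1, abs=0.15)

    def test_matches_gridsearch_likelihood_maximizer(self):
        # independent coarse-to-fine grid search of the log-likelihood
        rng = np.random.default_rng(8)
        n = 30
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.3 + 0.9 * x1 - 0.6 * x2)))
        y = rng.random(n) < p
        cohort = pd.DataFrame({"x1": x1, "x2": x2, "outcome": y})
        fitted = pm.fit_logistic(cohort, ModelSpec("grid", "outcome", ("x1", "x2")))

        X = np.column_stack([np.ones(n), x1, x2])
        yv = y.astype(float)

        def loglik(beta_grid):
            eta = np.tensordot(beta_grid, X, axes=([-1], [1]))
            return (yv * eta - np.log1p(np.exp(eta))).sum(axis=-1)

        center = np.zeros(3)
        width = 5.0
        for _ in range(8):
            axes = [np.linspace(c - width, c + width, 21) for c in center]
            grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
            ll = loglik(grid.reshape(-1, 3)).reshape(grid.shape[:-1])
            best = np.unravel_index(np.argmax(ll), ll.shape)
            center = grid[best]
            width /= 5.0
        est = np.array([fitted.coefficients[k] for k in ("intercept", "x1", "x2")])
        assert np.allclose(est, center, atol=1e-3)

    def test_rank_deficient_design_names_collinear_column(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        cohort = pd.DataFrame({"x": x, "x_copy": x, "outcome": x > 0})
        with pytest.raises(ValueError, match="collinear"):
            pm.fit_logistic(cohort, ModelSpec("bad", "outcome", ("x", "x_copy")))

    def test_missing_column_rejected(self, small_cohort):
        with pytest.raises(KeyError, match="no_such"):
            pm.fit_logistic(small_cohort.table, ModelSpec("m", "risk_group", ("no_such",)))


class TestRunModels:
    def test_trio_fits_on_fixture(self, small_cohort):
        with pytest.warns(UserWarning):  # n=12 with 5 covariates separates
            results = pm.run_models(small_cohort.table)
        assert set(results) == {"clinical", "mvm", "combined"}
        for _, roc in results.values():
            assert 0.0 <= roc.auc <= 1.0

    def test_outcome_independent_of_everything_gives_null_aucs(self):
        rng = np.random.default_rng(19)
        n = 4000
        cohort = pd.DataFrame(
            {
                "maternal_age": rng.normal(32, 6, n),
                "gestational_weight_gain": rng.normal(14, 7, n),
                "sbp_delivery": rng.normal(152, 25, n),
                "dbp_delivery": rng.normal(93, 13, n),
                "ga_delivery": rng.normal(35, 4, n),
                "mvm_score": rng.integers(0, 15, n),
                "risk_group": np.where(rng.random(n) < 0.6, "high", "low"),
            }
        )
        results = pm.run_models(cohort)
        for _, roc in results.values():
            assert roc.auc == pytest.approx(0.5, abs=0.03)

    def test_bp_mode_changes_clinical_covariates(self):
        specs = {s.name: s for s in pm.default_model_specs(bp_mode="systolic")}
        assert "dbp_delivery" not in specs["clinical"].covariates
        assert "sbp_delivery" in specs["clinical"].covariates
        with pytest.raises(ValueError):
            pm.default_model_specs(bp_mode="bad")
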