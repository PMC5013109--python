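"""Logistic respecification: design building, IRLS fit, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from grace_recal.errors import (
    DegenerateOutcomeError,
    PreconditionError,
    RankError,
    SeparationError,
)
from grace_recal.respec import (
    Design,
    ModelSpec,
    bootstrap_fit,
    build_design,
    fit_logistic,
    predict_prob,
)
from grace_recal.synthetic import GeneratorConfig, generate_cohort

from conftest import make_cohort


class TestBuildDesign:
    @pytest.mark.parametrize("variables,n_terms", [
        ("grace", 9),           # intercept + 8
        ("grace+smoking", 11),  # + ex/current indicators
        ("grace+copd", 10),     # + copd flag
    ])
    def test_term_counts(self, variables, n_terms, medium_cohort):
        design = build_design(medium_cohort, ModelSpec(variables))
        assert len(design.terms) == n_terms
        assert design.terms[0] == "intercept"
        assert design.X.shape == (len(medium_cohort), n_terms)

    def test_extra_terms_appended(self, medium_cohort):
        design = build_design(medium_cohort, ModelSpec("grace+copd", extra=("diabetes",)))
        assert design.terms[-1] == "diabetes"

    def test_incomplete_records_dropped_and_counted(self, medium_cohort):
        cohort = medium_cohort.copy()
        cohort.loc[cohort.index[:7], "creatinine"] = np.nan
        design = build_design(cohort, ModelSpec("grace"))
        assert design.n_dropped == 7
        assert design.X.shape[0] == len(cohort) - 7

    def test_constant_outcome_rejected(self):
        cohort = make_cohort([{"died_6m": False} for _ in range(20)])
        with pytest.raises(DegenerateOutcomeError):
            build_design(cohort, ModelSpec("grace"))


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1.0] * 25 + [0.0] * 75)
        design = Design(X=np.ones((100, 1)), y=y, terms=("intercept",),
                        n_dropped=0, index=np.arange(100))
        fit = fit_logistic(design)
        assert fit.coef["intercept"] == pytest.approx(np.log(0.25 / 0.75), abs=1e-8)

    def test_perfect_separation_detected(self):
        x = np.array([0.0] * 25 + [1.0] * 25)
        y = x.copy()
        design = Design(X=np.column_stack([np.ones(50), x]), y=y,
                        terms=("intercept", "x"), n_dropped=0, index=np.arange(50))
        with pytest.raises(SeparationError):
            fit_logistic(design)

    def test_singular_design_rejected(self):
        x = np.ones(40)
        y = np.array([0.0, 1.0] * 20)
        design = Design(X=np.column_stack([np.ones(40), x]), y=y,
                        terms=("intercept", "x"), n_dropped=0, index=np.arange(40))
        with pytest.raises(RankError):
            fit_logistic(design)

    def test_matches_grid_search_oracle_on_toy(self):
        # coarse-to-fine grid maximisation of the Bernoulli log-likelihood
        rng = np.random.default_rng(42)
        n = 50
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = (rng.random(n) < expit(-0.3 + 0.8 * x1 - 0.5 * x2)).astype(float)
        X = np.column_stack([np.ones(n), x1, x2])

        def loglik(beta):
            p = expit(X @ beta)
            return np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))

        centre = np.zeros(3)
        width = 4.0
        for _ in range(24):  # bisecting grid: final spacing ~4/2^24 << 1e-4
            axes = [np.linspace(c - width, c + width, 5) for c in centre]
            grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
            centre = grid[np.argmax([loglik(b) for b in grid])]
            width /= 2.0
        design = Design(X=X, y=y, terms=("intercept", "x1", "x2"),
                        n_dropped=0, index=np.arange(n))
        fit = fit_logistic(design)
        np.testing.assert_allclose(fit.beta, centre, atol=1e-4)
        assert loglik(fit.beta) >= loglik(centre) - 1e-8

    def test_needs_more_rows_than_terms(self):
        design = Design(X=np.ones((2, 3)), y=np.array([0.0, 1.0]),
                        terms=("a", "b", "c"), n_dropped=0, index=np.arange(2))
        with pytest.raises(PreconditionError):
            fit_logistic(design)


class TestPredict:
    def test_zero_linear_predictor_is_half(self):
        fit_terms = ("intercept",)
        design = Design(X=np.ones((100, 1)),
                        y=np.array([1.0] * 50 + [0.0] * 50),
                        terms=fit_terms, n_dropped=0, index=np.arange(100))
        fit = fit_logistic(design)
        assert predict_prob(fit, np.ones((1, 1)))[0] == pytest.approx(0.5, abs=1e-6)

    def test_intercept_only_returns_event_rate(self):
        y = np.array([1.0] * 25 + [0.0] * 75)
        design = Design(X=np.ones((100, 1)), y=y, terms=("intercept",),
                        n_dropped=0, index=np.arange(100))
        fit = fit_logistic(design)
        assert predict_prob(fit, np.ones((1, 1)))[0] == pytest.approx(0.25, abs=1e-8)

    def test_monotone_in_positive_coefficient_term(self, medium_cohort):
        design = build_design(medium_cohort, ModelSpec("grace"))
        fit = fit_logistic(design)
        row = design.X[:1].copy()
        i_age = design.terms.index("age")
        assert fit.coef["age"] > 0  # age is a strong mortality predictor
        lo = row.copy()
        hi = row.copy()
        hi[0, i_age] += 1.0
        assert predict_prob(fit, hi)[0] > predict_prob(fit, lo)[0]


class TestRecovery:
    def test_parameters_recovered_within_3se(self):
        # generator-faithfulness: fit the full truth (GRACE + COPD + diabetes)
        from grace_recal.synthetic import true_coefficients

        cfg = GeneratorConfig(n=50_000, seed=77)
        cohort = generate_cohort(cfg)
        design = build_design(cohort, ModelSpec("grace+copd", extra=("diabetes",)))
        fit = fit_logistic(design)
        truth = true_coefficients(cfg)
        for term in fit.terms:
            assert abs(fit.coef[term] - truth[term]) < 3 * fit.se[term], term

    def test_fitted_loglik_beats_truth(self):
        from grace_recal.synthetic import linear_predictor

        cfg = GeneratorConfig(n=5_000, seed=78)
        cohort = generate_cohort(cfg)
        design = build_design(cohort, ModelSpec("grace+copd", extra=("diabetes",)))
        fit = fit_logistic(design)
        lp_true = linear_predictor(cohort, cfg)
        p_true = expit(lp_true)
        y = design.y
        ll_true = np.sum(y * np.log(p_true) + (1 - y) * np.log1p(-p_true))
        assert fit.loglik >= ll_true

    def test_adding_a_term_never_decreases_loglik(self, medium_cohort):
        base = fit_logistic(build_design(medium_cohort, ModelSpec("grace")))
        plus = fit_logistic(build_design(medium_cohort, ModelSpec("grace+copd")))
        assert plus.loglik >= base.loglik - 1e-6


class TestBootstrap:
    def test_deterministic_given_seed(self, medium_cohort):
        design = build_design(medium_cohort.head(500), ModelSpec("grace"))
        a = bootstrap_fit(design, reps=3, seed=5)
        b = bootstrap_fit(design, reps=3, seed=5)
        assert a.mean == b.mean and a.sd == b.sd

    def test_bookkeeping_reps_and_positive_sd(self):
        rng = np.random.default_rng(13)
        n = 200
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = (rng.random(n) < expit(-0.5 + 0.6 * x1 + 0.3 * x2)).astype(float)
        design = Design(X=np.column_stack([np.ones(n), x1, x2]), y=y,
                        terms=("intercept", "x1", "x2"), n_dropped=0,
                        index=np.arange(n))
        boot = bootstrap_fit(design, reps=100, seed=1)
        assert boot.reps_done + boot.reps_failed == 100
        assert boot.estimates.shape[0] == boot.reps_done
        assert all(s > 0 for s in boot.sd.values())

    def test_means_within_3sd_of_full_sample(self, medium_cohort):
        design = build_design(medium_cohort, ModelSpec("grace"))
        fit = fit_logistic(design)
        boot = bootstrap_fit(design, reps=30, seed=2)
        for term in fit.terms:
            assert abs(boot.mean[term] - fit.coef[term]) < 3 * boot.sd[term], term

    def test_reps_must_be_positive(self, medium_cohort):
        design = build_design(medium_cohort.head(100), ModelSpec("grace"))
        with pytest.raises(PreconditionError):
            bootstrap_fit(design, reps=0)
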