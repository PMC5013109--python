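"""Logistic respecification of the risk model on registry-style data.

Instead of the published nomogram, the 6-month death outcome is refit by
maximum likelihood on the eight GRACE inputs (continuous covariates entered
linearly after standardisation with the fixed reference constants in
:mod:`grace_recal.scaling`), optionally extended with smoking history (two
indicators vs never) or the COPD flag.  Fitting is iteratively reweighted
least squares (statsmodels GLM, binomial family) behind this module's
surface, with explicit separation and rank checks.  A case-resampling
bootstrap provides internal validation of the parameter estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from grace_recal.cohort import GRACE_VARIABLES, identify_copd
from grace_recal.errors import (
    DegenerateOutcomeError,
    PreconditionError,
    RankError,
    SeparationError,
)
from grace_recal.scaling import standardise

CONTINUOUS = ("age", "heart_rate", "systolic_bp", "creatinine")
BINARY = ("diuretic_in_hospital", "cardiac_arrest", "st_deviation", "elevated_markers")

#: |beta| beyond this (standardised scale) is treated as diverging -> separation
SEPARATION_BETA_LIMIT = 15.0


@dataclass(frozen=True)
class ModelSpec:
    """Which covariate set to fit.

    ``variables`` is one of ``"grace"`` (the eight GRACE inputs),
    ``"grace+smoking"`` (plus ex/current indicators vs never) or
    ``"grace+copd"`` (plus the derived COPD indicator).  ``extra`` names
    additional boolean cohort columns to adjust for (e.g. ``("diabetes",)``).
    """

    variables: str = "grace"
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.variables not in ("grace", "grace+smoking", "grace+copd"):
            raise ValueError(f"unknown model spec: {self.variables}")


@dataclass
class Design:
    """A named design matrix plus outcome, after complete-case filtering."""

    X: np.ndarray  # (n, p) including leading intercept column
    y: np.ndarray  # (n,) 0/1
    terms: tuple[str, ...]  # column names, terms[0] == "intercept"
    n_dropped: int
    index: np.ndarray  # positions of used rows in the source cohort


@dataclass
class LogisticFit:
    coef: dict[str, float]
    se: dict[str, float]
    loglik: float
    n_used: int
    converged: bool
    terms: tuple[str, ...]

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.coef[t] for t in self.terms])


def build_design(cohort: pd.DataFrame, spec: ModelSpec) -> Design:
    """Assemble the standardised design matrix for a model specification.

    Records missing any needed variable (or the outcome) are dropped and
    counted.  Raises :class:`DegenerateOutcomeError` if the retained outcome
    is constant.
    """
    needed = list(GRACE_VARIABLES) + ["died_6m"]
    if spec.variables == "grace+smoking":
        needed.append("smoking")
    if spec.variables == "grace+copd":
        needed += ["oad_indicator", "smoking"]
    needed += list(spec.extra)

    complete = cohort[needed].notna().all(axis=1)
    used = cohort[complete]
    n_dropped = int((~complete).sum())
    if len(used) == 0:
        raise PreconditionError("no complete-case records for this model")

    cols: list[np.ndarray] = [np.ones(len(used))]
    terms: list[str] = ["intercept"]
    for var in CONTINUOUS:
        cols.append(standardise(used[var].to_numpy(dtype=float), var))
        terms.append(var)
    for var in BINARY:
        cols.append(used[var].to_numpy(dtype=float))
        terms.append(var)
    if spec.variables == "grace+smoking":
        cols.append((used["smoking"] == "ex").to_numpy(dtype=float))
        terms.append("smoking_ex")
        cols.append((used["smoking"] == "current").to_numpy(dtype=float))
        terms.append("smoking_current")
    if spec.variables == "grace+copd":
        cols.append(identify_copd(used).to_numpy(dtype=float))
        terms.append("copd")
    for var in spec.extra:
        cols.append(used[var].to_numpy(dtype=float))
        terms.append(var)

    y = used["died_6m"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise DegenerateOutcomeError("outcome is constant in the complete-case records")
    return Design(
        X=np.column_stack(cols),
        y=y,
        terms=tuple(terms),
        n_dropped=n_dropped,
        index=np.flatnonzero(complete.to_numpy()),
    )


def fit_logistic(design: Design, tol: float = 1e-8, max_iter: int = 100) -> LogisticFit:
    """Maximum-likelihood logistic fit (IRLS) with separation/rank guards."""
    X, y = design.X, design.y
    if len(y) <= X.shape[1]:
        raise PreconditionError("need more observations than parameters")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankError("design matrix is rank deficient")

    model = sm.GLM(y, X, family=sm.families.Binomial())
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation surfaces as huge betas, checked below
        try:
            res = model.fit(maxiter=max_iter, tol=tol, scale=1.0)
        except Exception as exc:  # statsmodels raises PerfectSeparationError on clean cases
            if "separation" in type(exc).__name__.lower() or "Perfect" in type(exc).__name__:
                raise SeparationError(str(exc)) from exc
            raise

    beta = np.asarray(res.params, dtype=float)
    if np.max(np.abs(beta)) > SEPARATION_BETA_LIMIT or not np.all(np.isfinite(beta)):
        raise SeparationError(
            f"diverging coefficients (max |beta| = {np.max(np.abs(beta)):.1f}); "
            "likely perfect separation"
        )
    se = np.sqrt(np.diag(res.cov_params()))
    return LogisticFit(
        coef=dict(zip(design.terms, beta)),
        se=dict(zip(design.terms, se)),
        loglik=float(res.llf),
        n_used=len(y),
        converged=bool(res.converged),
        terms=design.terms,
    )


def predict_prob(fit: LogisticFit, X: np.ndarray) -> np.ndarray:
    """Inverse-logit of the linear predictor for design rows ``X``."""
    from scipy.special import expit

    return expit(np.asarray(X) @ fit.beta)


def predict_cohort_model(cohort: pd.DataFrame, spec: ModelSpec,
                         fit: LogisticFit | None = None) -> tuple[pd.Series, LogisticFit, int]:
    """Fit (unless given) and predict death risk for all complete-case records.

    Returns predictions indexed like the usable subset of ``cohort``, the fit,
    and the dropped-record count.
    """
    design = build_design(cohort, spec)
    if fit is None:
        fit = fit_logistic(design)
    p = predict_prob(fit, design.X)
    idx = cohort.index[design.index]
    return pd.Series(p, index=idx, name="risk"), fit, design.n_dropped


@dataclass
class BootstrapSummary:
    mean: dict[str, float]
    sd: dict[str, float]
    ci_low: dict[str, float]  # 2.5th percentile
    ci_high: dict[str, float]  # 97.5th percentile
    reps_done: int
    reps_failed: int
    estimates: np.ndarray  # (reps_done, p)
    terms: tuple[str, ...]


def bootstrap_fit(design: Design, reps: int = 100, seed: int = 0,
                  tol: float = 1e-8, max_iter: int = 100) -> BootstrapSummary:
    """Case-resampling bootstrap of the logistic fit.

    Whole records are resampled with replacement; non-converged or separated
    replicates are counted and skipped.  Reproducible given ``seed``.
    """
    if reps < 1:
        raise PreconditionError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(design.y)
    rows = []
    failed = 0
    for _ in range(reps):
        take = rng.integers(0, n, size=n)
        boot = Design(X=design.X[take], y=design.y[take], terms=design.terms,
                      n_dropped=0, index=take)
        try:
            if boot.y.min() == boot.y.max():
                raise DegenerateOutcomeError("constant outcome in resample")
            fit = fit_logistic(boot, tol=tol, max_iter=max_iter)
        except (SeparationError, RankError, DegenerateOutcomeError):
            failed += 1
            continue
        rows.append(fit.beta)
    if not rows:
        raise SeparationError("all bootstrap replicates failed")
    est = np.vstack(rows)
    lo, hi = np.percentile(est, [2.5, 97.5], axis=0)
    terms = design.terms
    return BootstrapSummary(
        mean=dict(zip(terms, est.mean(axis=0))),
        sd=dict(zip(terms, est.std(axis=0, ddof=1) if len(rows) > 1 else np.zeros(est.shape[1]))),
        ci_low=dict(zip(terms, lo)),
        ci_high=dict(zip(terms, hi)),
        reps_done=len(rows),
        reps_failed=failed,
        estimates=est,
        terms=terms,
    )
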