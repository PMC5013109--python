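"""Decile stratification and the Mantel-Haenszel pooled risk ratio.

The central estimand of the validation: the average relative risk of 6-month
death for the subgroup (COPD) versus the rest, *conditional on predicted
risk*.  Predictions are pooled (both groups together) into deciles; within
each decile a 2x2 table of death by group is formed; the Mantel-Haenszel
estimator pools the per-stratum risk ratios

    RR_MH = [ sum_k a_k * n0_k / N_k ] / [ sum_k b_k * n1_k / N_k ]

with a_k deaths among n1_k exposed (subgroup) and b_k deaths among n0_k
unexposed in stratum k, N_k = n1_k + n0_k.  If the score is equally
well-calibrated in both groups the pooled RR is 1; RR > 1 means the score
underestimates the subgroup's risk.  The 95% CI uses the Greenland-Robins
variance of log RR with normal-theory bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from grace_recal.errors import PreconditionError, UndefinedStatisticError
from grace_recal.nomogram import BANDS, RiskBandConfig

Z_95 = 1.959963984540054


@dataclass(frozen=True)
class StratumTable:
    """One stratum's 2x2 counts: deaths/survivors x exposed/unexposed."""

    a: int  # deaths among exposed
    n1: int  # exposed total
    b: int  # deaths among unexposed
    n0: int  # unexposed total

    def __post_init__(self) -> None:
        if not (0 <= self.a <= self.n1 and 0 <= self.b <= self.n0):
            raise ValueError("stratum counts out of range")
        if self.n1 + self.n0 < 1:
            raise ValueError("empty stratum")

    @property
    def N(self) -> int:
        return self.n1 + self.n0


@dataclass(frozen=True)
class MHResult:
    rr: float
    ci_low: float
    ci_high: float
    n_strata: int
    n_strata_dropped: int = 0

    def as_dict(self) -> dict:
        return {
            "rr": self.rr,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_strata": self.n_strata,
            "n_strata_dropped": self.n_strata_dropped,
        }


def assign_deciles(risks, n_bins: int = 10) -> np.ndarray:
    """Rank-based equal-count decile labels (1-10) over pooled predictions.

    Ties are broken by stable input order, so bin sizes differ by at most one
    even when predictions are heavily tied.
    """
    risks = np.asarray(risks, dtype=float)
    n = len(risks)
    if n < n_bins:
        raise PreconditionError(f"need at least {n_bins} observations, got {n}")
    order = np.argsort(risks, kind="stable")
    # rank r (0-based) -> bin floor(r * n_bins / n) gives sizes differing by <= 1
    bins = (np.arange(n) * n_bins) // n + 1
    labels = np.empty(n, dtype=int)
    labels[order] = bins
    return labels


def stratum_tables(deciles, group_flag, outcomes) -> list[StratumTable]:
    """Tabulate per-stratum 2x2 counts; one table per non-empty stratum."""
    deciles = np.asarray(deciles)
    group = np.asarray(group_flag, dtype=bool)
    died = np.asarray(outcomes, dtype=bool)
    if not (len(deciles) == len(group) == len(died)):
        raise PreconditionError("deciles, group_flag and outcomes must have equal length")
    tables = []
    for k in np.unique(deciles):
        in_k = deciles == k
        g = group[in_k]
        d = died[in_k]
        tables.append(StratumTable(
            a=int((g & d).sum()), n1=int(g.sum()),
            b=int((~g & d).sum()), n0=int((~g).sum()),
        ))
    return tables


def mh_pooled_rr(strata: list[StratumTable]) -> MHResult:
    """Mantel-Haenszel pooled risk ratio with Greenland-Robins 95% CI.

    Strata where either group is empty contribute nothing to the defining
    sums; they are dropped and counted in ``n_strata_dropped``.
    """
    usable = [s for s in strata if s.n1 > 0 and s.n0 > 0]
    dropped = len(strata) - len(usable)
    if not usable:
        raise UndefinedStatisticError("no stratum has both groups represented")

    num = sum(s.a * s.n0 / s.N for s in usable)
    den = sum(s.b * s.n1 / s.N for s in usable)
    if den == 0.0:
        raise UndefinedStatisticError("no deaths among the unexposed in any stratum: RR undefined")
    rr = num / den

    if num == 0.0:
        # no exposed deaths anywhere: point estimate 0, CI degenerate
        return MHResult(rr=0.0, ci_low=0.0, ci_high=math.nan,
                        n_strata=len(usable), n_strata_dropped=dropped)

    # Greenland-Robins variance of log RR
    var_num = sum(((s.a + s.b) * s.n1 * s.n0 / s.N**2 - s.a * s.b / s.N) for s in usable)
    var = var_num / (num * den)
    se = math.sqrt(max(var, 0.0))
    log_rr = math.log(rr)
    return MHResult(
        rr=rr,
        ci_low=math.exp(log_rr - Z_95 * se),
        ci_high=math.exp(log_rr + Z_95 * se),
        n_strata=len(usable),
        n_strata_dropped=dropped,
    )


def decile_adjusted_rr(risks, group_flag, outcomes) -> MHResult:
    """Convenience: pooled deciles of ``risks`` -> strata -> M-H pooled RR."""
    deciles = assign_deciles(risks)
    return mh_pooled_rr(stratum_tables(deciles, group_flag, outcomes))


def observed_vs_predicted_by_decile(predictions, outcomes, group_flag) -> pd.DataFrame:
    """Per-decile mean predicted risk (pooled) and observed mortality by group.

    Observed mortality is NaN (not 0) in deciles where a group has no members.
    """
    risks = np.asarray(predictions, dtype=float)
    died = np.asarray(outcomes, dtype=bool)
    group = np.asarray(group_flag, dtype=bool)
    if len(risks) == 0:
        raise PreconditionError("empty input")
    deciles = assign_deciles(risks)
    rows = []
    for k in np.unique(deciles):
        in_k = deciles == k
        g, d = group[in_k], died[in_k]
        rows.append({
            "decile": int(k),
            "mean_predicted": float(risks[in_k].mean()),
            "observed_non_group": float(d[~g].mean()) if (~g).any() else math.nan,
            "observed_group": float(d[g].mean()) if g.any() else math.nan,
            "n": int(in_k.sum()),
        })
    return pd.DataFrame(rows)


def observed_by_band(predictions, outcomes, group_flag,
                     bands: RiskBandConfig | None = None) -> pd.DataFrame:
    """Observed mortality per risk band x group; NaN where a cell is empty."""
    bands = bands or RiskBandConfig()
    risks = np.asarray(predictions, dtype=float)
    died = np.asarray(outcomes, dtype=bool)
    group = np.asarray(group_flag, dtype=bool)
    if len(risks) == 0:
        raise PreconditionError("empty input")
    band = np.where(risks < bands.low_upper, "low",
                    np.where(risks <= bands.moderate_upper, "moderate", "high"))
    rows = []
    for b in BANDS:
        in_b = band == b
        g, d = group[in_b], died[in_b]
        rows.append({
            "band": b,
            "observed_non_group": float(d[~g].mean()) if (in_b.any() and (~g).any()) else math.nan,
            "observed_group": float(d[g].mean()) if (in_b.any() and g.any()) else math.nan,
            "n_non_group": int((~g).sum()) if in_b.any() else 0,
            "n_group": int(g.sum()) if in_b.any() else 0,
        })
    return pd.DataFrame(rows)
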