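"""Discrimination and calibration metrics for binary risk models.

* C-statistic: probability a random event outranks a random non-event, ties
  counted 1/2 (the Mann-Whitney construction; equals the ROC AUC).
* DeLong's paired asymptotic test for comparing two C-statistics computed on
  the same records (structural-components covariance).
* Hosmer-Lemeshow chi-square over deciles of predicted risk, df = g - 2.
* Continuous net reclassification improvement (NRI): net share of events whose
  predicted risk increases plus net share of non-events whose risk decreases
  when moving from an old to a new model; z from the multinomial variance.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from grace_recal.errors import DegenerateOutcomeError, PreconditionError, UndefinedStatisticError


def _split(predictions, outcomes) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if len(p) != len(y):
        raise PreconditionError("predictions and outcomes must have equal length")
    if y.all() or not y.any():
        raise DegenerateOutcomeError("need at least one event and one non-event")
    return p[y], p[~y]


def _placement_values(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components: V10 (per event), V01 (per non-event), AUC."""
    # midranks via average ranking of the pooled sample
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    v10 = (ranks[:m] - rank_pos) / n
    v01 = 1.0 - (ranks[m:] - rank_neg) / m
    auc = v10.mean()
    return v10, v01, float(auc)


def c_statistic(predictions, outcomes) -> float:
    """Mann-Whitney C-statistic (ties counted 1/2)."""
    pos, neg = _split(predictions, outcomes)
    _, _, auc = _placement_values(pos, neg)
    return auc


def compare_c_statistics(pred_a, pred_b, outcomes) -> tuple[float, float]:
    """DeLong's paired test for C(model a) - C(model b) on the same records.

    Returns ``(difference, two_sided_p)``.  Identical prediction vectors give
    difference 0 and p = 1.
    """
    pa = np.asarray(pred_a, dtype=float)
    pb = np.asarray(pred_b, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if not (len(pa) == len(pb) == len(y)):
        raise PreconditionError("paired predictions must cover the same records")
    if y.all() or not y.any():
        raise DegenerateOutcomeError("need at least one event and one non-event")

    v10a, v01a, auc_a = _placement_values(pa[y], pa[~y])
    v10b, v01b, auc_b = _placement_values(pb[y], pb[~y])
    m, n = int(y.sum()), int((~y).sum())
    diff = auc_a - auc_b
    if np.array_equal(pa, pb):
        return 0.0, 1.0
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        # rank-identical models: no sampling variability in the difference
        return float(diff), 1.0 if math.isclose(diff, 0.0, abs_tol=1e-12) else 0.0
    z = diff / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(diff), float(p)


def hosmer_lemeshow(predictions, outcomes, g: int = 10) -> tuple[float, int, float]:
    """Hosmer-Lemeshow goodness-of-fit over g groups of predicted risk.

    Groups are equal-count bins of the predictions (stable tie handling);
    statistic = sum_g (O_g - E_g)^2 / (n_g * pbar_g * (1 - pbar_g)),
    df = g - 2, p from the chi-square upper tail.
    """
    from grace_recal.mh import assign_deciles

    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=bool).astype(float)
    if len(p) < g:
        raise PreconditionError(f"need at least g={g} observations")
    if y.sum() == 0:
        raise DegenerateOutcomeError("need at least one event")
    groups = assign_deciles(p, n_bins=g)
    stat = 0.0
    for k in np.unique(groups):
        in_k = groups == k
        n_k = int(in_k.sum())
        pbar = float(p[in_k].mean())
        if pbar <= 0.0 or pbar >= 1.0:
            raise UndefinedStatisticError(
                f"group {k} has mean predicted risk {pbar}; reduce g or trim predictions"
            )
        o_k = float(y[in_k].sum())
        e_k = n_k * pbar
        stat += (o_k - e_k) ** 2 / (n_k * pbar * (1.0 - pbar))
    df = g - 2
    return float(stat), int(df), float(stats.chi2.sf(stat, df))


def continuous_nri(pred_old, pred_new, outcomes) -> tuple[float, float, float]:
    """Continuous net reclassification improvement between two models.

    NRI = [P(up|event) - P(down|event)] + [P(down|non-event) - P(up|non-event)]
    where up/down means any increase/decrease in predicted risk; exact ties
    count as neither.  Returns ``(nri, z, two_sided_p)`` with z from the
    multinomial variance of the two net proportions.
    """
    po = np.asarray(pred_old, dtype=float)
    pn = np.asarray(pred_new, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if not (len(po) == len(pn) == len(y)):
        raise PreconditionError("paired predictions must cover the same records")
    if y.all() or not y.any():
        raise DegenerateOutcomeError("need at least one event and one non-event")

    up = pn > po
    down = pn < po
    n_e = int(y.sum())
    n_ne = int((~y).sum())
    p_up_e = up[y].mean()
    p_down_e = down[y].mean()
    p_up_ne = up[~y].mean()
    p_down_ne = down[~y].mean()
    nri_e = p_up_e - p_down_e
    nri_ne = p_down_ne - p_up_ne
    nri = nri_e + nri_ne

    var = (p_up_e + p_down_e - nri_e**2) / n_e + (p_up_ne + p_down_ne - nri_ne**2) / n_ne
    if var <= 0:
        z = 0.0 if nri == 0 else math.inf * np.sign(nri)
        p = 1.0 if nri == 0 else 0.0
        return float(nri), float(z), float(p)
    z = nri / math.sqrt(var)
    return float(nri), float(z), float(2.0 * stats.norm.sf(abs(z)))
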