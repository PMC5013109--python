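"""Multiplicative subgroup recalibration and reclassification accounting.

The simplest fix for a subgroup whose risk a score systematically
underestimates: multiply the subgroup's predicted risks by a constant factor
f (the decile-adjusted Mantel-Haenszel RR estimated from the same data, e.g.
1.3 for COPD), cap at 1, and re-band.  Because the bands are 3% and 6%, any
f < 2 can move a low-risk patient at most one band up (0.03 * f < 0.06), so
the low-to-high cell of the reclassification matrix is structurally zero, and
f >= 1 can never move anyone down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from grace_recal.errors import ConfigError, UndefinedStatisticError
from grace_recal.mh import MHResult, assign_deciles, decile_adjusted_rr
from grace_recal.nomogram import BANDS, RiskBandConfig


@dataclass(frozen=True)
class RecalibrationSpec:
    """Multiplier f applied to the target group's predicted risks."""

    multiplier: float = 1.3
    cap_at_one: bool = True

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ConfigError("multiplier must be positive")


def recalibrate(risks, group_flag, spec: RecalibrationSpec) -> np.ndarray:
    """Multiply group members' risks by f (capped at 1); others pass unchanged."""
    risks = np.asarray(risks, dtype=float)
    group = np.asarray(group_flag, dtype=bool)
    out = risks.copy()
    out[group] = risks[group] * spec.multiplier
    if spec.cap_at_one:
        np.minimum(out, 1.0, out=out)
    return out


def estimate_multiplier(risks, group_flag, outcomes) -> MHResult:
    """The data-estimated multiplier: the decile-adjusted M-H pooled RR."""
    return decile_adjusted_rr(risks, group_flag, outcomes)


def reclassification_matrix(bands_before, bands_after) -> pd.DataFrame:
    """3x3 cross-tabulation of risk bands before vs after a modification.

    Returns counts with band-ordered rows/columns plus a ``row_pct`` companion
    accessible via ``attrs["row_pct"]``.
    """
    before = pd.Categorical(bands_before, categories=BANDS, ordered=True)
    after = pd.Categorical(bands_after, categories=BANDS, ordered=True)
    if len(before) != len(after):
        raise ValueError("bands_before and bands_after must have equal length")
    counts = pd.crosstab(before, after, dropna=False)
    counts = counts.reindex(index=BANDS, columns=BANDS, fill_value=0)
    counts.index.name = "before"
    counts.columns.name = "after"
    row_tot = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        row_pct = counts.div(row_tot.replace(0, np.nan), axis=0) * 100.0
    counts.attrs["row_pct"] = row_pct
    return counts


def deaths_by_decile(risks, outcomes, group_flag=None) -> np.ndarray:
    """Share of the group's deaths falling in each decile of predicted risk.

    Deciles are assigned on the pooled predictions; proportions are over the
    selected group's deaths and sum to 1.  A well-stratifying model
    concentrates deaths in the top deciles (a steeply increasing vector).
    """
    risks = np.asarray(risks, dtype=float)
    died = np.asarray(outcomes, dtype=bool)
    deciles = assign_deciles(risks)
    if group_flag is not None:
        sel = np.asarray(group_flag, dtype=bool)
    else:
        sel = np.ones(len(risks), dtype=bool)
    total = int((died & sel).sum())
    if total == 0:
        raise UndefinedStatisticError("no deaths in the selected group")
    shares = np.array([
        int((died & sel & (deciles == k)).sum()) / total for k in range(1, 11)
    ])
    return shares
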