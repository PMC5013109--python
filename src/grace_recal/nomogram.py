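"""Table-driven nomogram scoring for GRACE-style risk models.

A nomogram maps each covariate to points (step functions over breakpoint
intervals for continuous variables, fixed points for binary ones), sums the
points into a total score, and converts the score to a predicted 6-month
death probability via a piecewise-linear score-to-risk curve.  Predicted risk
is then stratified into the guideline bands low (<3%), moderate (3%-6%) and
high (>6%) that drive treatment-intensity recommendations after non-STEMI and
unstable angina.

The heart-failure term of the score uses in-hospital diuretic prescription as
a proxy (the "mini-GRACE" convention for registries that do not record Killip
class).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from grace_recal.cohort import GRACE_VARIABLES
from grace_recal.errors import ConfigError, PipelineError, PreconditionError

BANDS = ("low", "moderate", "high")

#: Boolean GRACE inputs (fixed points when true, 0 when false).
BOOLEAN_VARIABLES = ("diuretic_in_hospital", "cardiac_arrest", "st_deviation", "elevated_markers")
CONTINUOUS_VARIABLES = ("age", "heart_rate", "systolic_bp", "creatinine")


@dataclass(frozen=True)
class RiskBandConfig:
    """Risk-band thresholds on the probability scale.

    Boundary convention (the published band labels "<3%", "3%-6%", ">6%" do
    not pin down exact-boundary membership): low = [0, low_upper),
    moderate = [low_upper, moderate_upper], high = (moderate_upper, 1].
    """

    low_upper: float = 0.03
    moderate_upper: float = 0.06

    def __post_init__(self) -> None:
        if not 0.0 < self.low_upper < self.moderate_upper < 1.0:
            raise ConfigError("require 0 < low_upper < moderate_upper < 1")


@dataclass(frozen=True)
class PointTable:
    """Step-function point table for one continuous variable.

    ``breakpoints`` are the interval lower edges (strictly increasing);
    ``points[i]`` applies on [breakpoints[i], breakpoints[i+1]).  Values below
    the first breakpoint clamp to 0 points; values at or above the last
    breakpoint take the last interval's points.
    """

    breakpoints: tuple[float, ...]
    points: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.breakpoints) != len(self.points):
            raise ConfigError("breakpoints and points must have equal length")
        if len(self.breakpoints) == 0:
            raise ConfigError("point table cannot be empty")
        if any(b2 <= b1 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])):
            raise ConfigError("breakpoints must be strictly increasing")

    def lookup(self, value: float) -> float:
        idx = np.searchsorted(self.breakpoints, value, side="right") - 1
        if idx < 0:
            return 0.0  # clamp below the first interval
        return float(self.points[idx])


@dataclass(frozen=True)
class Nomogram:
    """Point tables plus the score-to-risk conversion curve."""

    continuous: Mapping[str, PointTable]
    boolean_points: Mapping[str, float]
    score_to_risk_curve: tuple[tuple[float, float], ...]  # (score, risk) anchors
    name: str = "unnamed"
    source: str = ""

    def __post_init__(self) -> None:
        curve = self.score_to_risk_curve
        if len(curve) < 2:
            raise ConfigError("score_to_risk_curve needs at least 2 anchors")
        scores = [s for s, _ in curve]
        risks = [r for _, r in curve]
        if any(s2 <= s1 for s1, s2 in zip(scores, scores[1:])):
            raise ConfigError("score anchors must be strictly increasing")
        if any(r2 < r1 for r1, r2 in zip(risks, risks[1:])):
            raise ConfigError("risk anchors must be non-decreasing")
        if any(not 0.0 <= r <= 1.0 for r in risks):
            raise ConfigError("risk anchors must lie in [0, 1]")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.continuous) + tuple(self.boolean_points)


def load_nomogram(path: str | Path) -> Nomogram:
    """Load a nomogram from its YAML config format.

    Continuous variables are arrays of ``{lower, points}`` (or
    ``{lower, upper, points}``; ``upper`` is informative only — intervals are
    defined by consecutive lower edges); booleans are ``{points}``; the curve
    is a list of ``{score, risk}`` anchors.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    continuous = {}
    for var, rows in raw.get("continuous", {}).items():
        rows = sorted(rows, key=lambda r: r["lower"])
        continuous[var] = PointTable(
            breakpoints=tuple(float(r["lower"]) for r in rows),
            points=tuple(float(r["points"]) for r in rows),
        )
    boolean_points = {var: float(spec["points"]) for var, spec in raw.get("boolean", {}).items()}
    curve = tuple((float(a["score"]), float(a["risk"])) for a in raw["score_to_risk"])
    return Nomogram(
        continuous=continuous,
        boolean_points=boolean_points,
        score_to_risk_curve=curve,
        name=raw.get("name", "unnamed"),
        source=raw.get("source", ""),
    )


def default_nomogram() -> Nomogram:
    """The nomogram shipped with the package (a synthetic mini-GRACE stand-in)."""
    return load_nomogram(Path(__file__).parent / "data" / "synthetic_mini_grace.yaml")


def points_for_variable(variable: str, value, nomogram: Nomogram) -> float:
    """Points contributed by one covariate value.

    Boolean variables contribute their fixed points when true and 0 when
    false; continuous variables contribute the points of the breakpoint
    interval containing the value (clamped at the table's ends).
    """
    if pd.isna(value):
        raise PreconditionError(f"missing value for {variable}")
    if variable in nomogram.boolean_points:
        return float(nomogram.boolean_points[variable]) if bool(value) else 0.0
    if variable in nomogram.continuous:
        return nomogram.continuous[variable].lookup(float(value))
    raise LookupError(f"variable not in nomogram: {variable}")


class ScoredAsMissing(Exception):
    """Raised when a record lacks a GRACE input; callers drop and count it."""


def grace_score(record: pd.Series | Mapping, nomogram: Nomogram) -> float:
    """Total nomogram score: the sum of per-variable points over all 8 inputs."""
    total = 0.0
    for var in nomogram.variables:
        value = record[var]
        if pd.isna(value):
            raise ScoredAsMissing(var)
        total += points_for_variable(var, value, nomogram)
    return total


def score_to_risk(score: float, nomogram: Nomogram) -> float:
    """Predicted death probability by linear interpolation of the anchor curve.

    Scores outside the anchor range clamp to the terminal risks.
    """
    scores = np.array([s for s, _ in nomogram.score_to_risk_curve])
    risks = np.array([r for _, r in nomogram.score_to_risk_curve])
    return float(np.interp(score, scores, risks))


def stratify_risk(risk: float, bands: RiskBandConfig | None = None) -> str:
    """Assign a predicted risk to the low / moderate / high treatment band."""
    bands = bands or RiskBandConfig()
    if not 0.0 <= risk <= 1.0:
        raise ValueError(f"risk must lie in [0, 1], got {risk}")
    if risk < bands.low_upper:
        return "low"
    if risk <= bands.moderate_upper:
        return "moderate"
    return "high"


def predict_cohort(cohort: pd.DataFrame, nomogram: Nomogram,
                   bands: RiskBandConfig | None = None) -> tuple[pd.DataFrame, int]:
    """Score every scoreable record; drop (and count) records missing any input.

    Returns a predictions frame (patient_id, score, risk, band) and the drop
    count.  Raises :class:`PipelineError` if no record is scoreable.
    """
    bands = bands or RiskBandConfig()
    needed = list(nomogram.variables)
    complete = cohort[needed].notna().all(axis=1)
    dropped = int((~complete).sum())
    usable = cohort[complete]
    if len(usable) == 0:
        raise PipelineError(f"no scoreable records (all {len(cohort)} missing a GRACE input)")

    scores = np.zeros(len(usable))
    for var in nomogram.continuous:
        table = nomogram.continuous[var]
        vals = usable[var].to_numpy(dtype=float)
        idx = np.searchsorted(table.breakpoints, vals, side="right") - 1
        pts = np.where(idx < 0, 0.0, np.asarray(table.points)[np.clip(idx, 0, None)])
        scores += pts
    for var, pts in nomogram.boolean_points.items():
        scores += pts * usable[var].to_numpy(dtype=float)

    anchors = np.array([s for s, _ in nomogram.score_to_risk_curve])
    risks_anchor = np.array([r for _, r in nomogram.score_to_risk_curve])
    risks = np.interp(scores, anchors, risks_anchor)
    band = np.where(risks < bands.low_upper, "low",
                    np.where(risks <= bands.moderate_upper, "moderate", "high"))
    pred = pd.DataFrame({
        "patient_id": usable["patient_id"].to_numpy(),
        "score": scores,
        "risk": risks,
        "band": band,
    }, index=usable.index)
    return pred, dropped
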