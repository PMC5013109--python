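"""End-to-end validation runs: base model, modifications, subgroups, strata.

``run_validation`` reproduces the full analysis shape on one cohort:

1. *normal score* — nomogram-based predictions, decile-adjusted M-H RR
   (subgroup vs rest), C-statistic, Hosmer-Lemeshow;
2. *normal score x f* — the subgroup's predictions multiplied by the
   data-estimated RR (or a fixed factor), deciles recomputed, plus
   reclassification and deaths-by-decile for the subgroup;
3. *registry-derived score* — logistic refit on the eight GRACE inputs;
4. *registry-derived + smoking*;
5. *registry-derived + subgroup indicator* — with the continuous NRI against
   model 3.

C-statistic comparisons follow the comparator pairing of the source design:
the multiplied score is compared with the normal score, and the augmented
refits with the plain refit.  No multiple-testing adjustment is applied; all
intervals and p-values are unadjusted.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from grace_recal import __version__
from grace_recal.cohort import apply_exclusions, identify_copd, read_cohort
from grace_recal.errors import PipelineError, PreconditionError
from grace_recal.metrics import c_statistic, compare_c_statistics, continuous_nri, hosmer_lemeshow
from grace_recal.mh import (
    decile_adjusted_rr,
    observed_by_band,
    observed_vs_predicted_by_decile,
)
from grace_recal.nomogram import Nomogram, RiskBandConfig, default_nomogram, predict_cohort
from grace_recal.recalibrate import (
    RecalibrationSpec,
    deaths_by_decile,
    recalibrate,
    reclassification_matrix,
)
from grace_recal.respec import ModelSpec, predict_cohort_model
from grace_recal.synthetic import GeneratorConfig, generate_cohort

logger = logging.getLogger("grace_recal")

ALL_MODELS = ("normal", "normal_x_f", "derived", "derived+smoking", "derived+group")


@dataclass
class RunConfig:
    """Configuration of one validation run."""

    cohort_path: str | None = None  # read a cohort CSV ...
    generator: GeneratorConfig | None = None  # ... or generate one
    nomogram: Nomogram | None = None  # default: shipped synthetic stand-in
    bands: RiskBandConfig = field(default_factory=RiskBandConfig)
    models: tuple[str, ...] = ALL_MODELS
    subgroup: str = "copd"  # "copd" (derived) or a boolean cohort column
    stratify_by: str | None = None  # None, "diagnosis" or "admission_year"
    multiplier: float | None = None  # None -> estimate from the data
    use_rounded_multiplier: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not self.models:
            raise PipelineError("at least one model must be requested")
        unknown = set(self.models) - set(ALL_MODELS)
        if unknown:
            raise PipelineError(f"unknown model(s): {sorted(unknown)}")


def _band_labels(risks: np.ndarray, bands: RiskBandConfig) -> np.ndarray:
    return np.where(risks < bands.low_upper, "low",
                    np.where(risks <= bands.moderate_upper, "moderate", "high"))


def _subgroup_flag(cohort: pd.DataFrame, subgroup: str) -> pd.Series:
    if subgroup == "copd":
        return identify_copd(cohort)
    if subgroup not in cohort.columns:
        raise PipelineError(f"subgroup column not in cohort: {subgroup}")
    flag = cohort[subgroup]
    if flag.isna().any():
        raise PipelineError(f"subgroup column {subgroup} has missing values")
    flag = flag.astype(bool)
    if flag.all() or not flag.any():
        raise PipelineError(f"subgroup column {subgroup} is constant")
    return flag


def _model_block(risks: pd.Series, cohort: pd.DataFrame, group: pd.Series,
                 bands: RiskBandConfig, comparator: pd.Series | None = None) -> dict:
    """Common per-model result block: M-H RR, C, HL, band table."""
    idx = risks.index
    y = cohort.loc[idx, "died_6m"].astype(bool).to_numpy()
    g = group.loc[idx].to_numpy()
    r = risks.to_numpy()
    block = {
        "n": int(len(r)),
        "mh": decile_adjusted_rr(r, g, y).as_dict(),
        "c_statistic": c_statistic(r, y),
        "hosmer_lemeshow": dict(zip(("statistic", "df", "p"), hosmer_lemeshow(r, y))),
        "observed_by_band": observed_by_band(r, y, g, bands).to_dict(orient="records"),
    }
    if comparator is not None:
        common = idx.intersection(comparator.index)
        diff, p = compare_c_statistics(
            risks.loc[common].to_numpy(), comparator.loc[common].to_numpy(),
            cohort.loc[common, "died_6m"].astype(bool).to_numpy(),
        )
        block["c_vs_comparator"] = {"difference": diff, "p": p}
    return block


def run_validation(config: RunConfig) -> dict:
    """Run the full validation; returns the report as a JSON-serialisable dict."""
    config.validate()
    if config.cohort_path is not None:
        cohort = read_cohort(config.cohort_path)
    else:
        gen = config.generator or GeneratorConfig(seed=config.seed)
        cohort = generate_cohort(gen)
    cohort, log = apply_exclusions(cohort)
    logger.info("exclusions: %s", log.as_dict())
    if len(cohort) == 0:
        raise PipelineError("exclusions removed every record")

    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "subgroup": config.subgroup,
            "config_hash": hashlib.sha256(
                repr((config.models, config.subgroup, config.multiplier,
                      config.use_rounded_multiplier, config.seed)).encode()
            ).hexdigest()[:16],
        },
        "exclusions": log.as_dict(),
        "models": {},
        "notes": ["p-values and CIs are unadjusted for multiple testing"],
    }

    if config.stratify_by:
        col = config.stratify_by
        if col not in ("diagnosis", "admission_year"):
            raise PipelineError(f"cannot stratify by: {col}")
        report["strata"] = {}
        for value, sub in cohort.groupby(col, observed=True):
            sub_cfg = RunConfig(**{**asdict_shallow(config), "stratify_by": None})
            report["strata"][str(value)] = _run_on_cohort(sub.reset_index(drop=True), sub_cfg)
        report["stratified_by"] = col
        # pooled record counts must reconcile with the full cohort
        report["n_pooled"] = int(sum(
            r["n_cohort"] for r in report["strata"].values()
        ))
        return report

    report.update(_run_on_cohort(cohort, config))
    return report


def asdict_shallow(config: RunConfig) -> dict:
    return {
        "cohort_path": config.cohort_path,
        "generator": config.generator,
        "nomogram": config.nomogram,
        "bands": config.bands,
        "models": config.models,
        "subgroup": config.subgroup,
        "stratify_by": config.stratify_by,
        "multiplier": config.multiplier,
        "use_rounded_multiplier": config.use_rounded_multiplier,
        "seed": config.seed,
    }


def _run_on_cohort(cohort: pd.DataFrame, config: RunConfig) -> dict:
    bands = config.bands
    nomogram = config.nomogram or default_nomogram()
    group = _subgroup_flag(cohort, config.subgroup)
    out: dict = {"n_cohort": int(len(cohort)), "models": {}}
    y_all = cohort["died_6m"].astype(bool)

    base_pred: pd.Series | None = None
    derived_pred: pd.Series | None = None

    if "normal" in config.models or "normal_x_f" in config.models:
        pred_df, dropped = predict_cohort(cohort, nomogram, bands)
        base_pred = pd.Series(pred_df["risk"].to_numpy(), index=pred_df.index)
        logger.info("stage=score n_scored=%d n_dropped=%d", len(base_pred), dropped)
        if "normal" in config.models:
            block = _model_block(base_pred, cohort, group, bands)
            block["n_dropped"] = dropped
            block["observed_vs_predicted_by_decile"] = observed_vs_predicted_by_decile(
                base_pred.to_numpy(), y_all.loc[base_pred.index].to_numpy(),
                group.loc[base_pred.index].to_numpy(),
            ).to_dict(orient="records")
            block["deaths_by_decile_group"] = deaths_by_decile(
                base_pred.to_numpy(), y_all.loc[base_pred.index].to_numpy(),
                group.loc[base_pred.index].to_numpy(),
            ).tolist()
            out["models"]["normal"] = block

    if "normal_x_f" in config.models:
        assert base_pred is not None
        idx = base_pred.index
        y = y_all.loc[idx].to_numpy()
        g = group.loc[idx].to_numpy()
        if config.multiplier is not None:
            factor_exact = float(config.multiplier)
        else:
            factor_exact = decile_adjusted_rr(base_pred.to_numpy(), g, y).rr
        factor_rounded = round(factor_exact, 1)
        factor = factor_rounded if config.use_rounded_multiplier else factor_exact
        recal = recalibrate(base_pred.to_numpy(), g,
                            RecalibrationSpec(multiplier=factor))
        recal_s = pd.Series(recal, index=idx)
        block = _model_block(recal_s, cohort, group, bands, comparator=base_pred)
        block["multiplier"] = {"applied": factor, "exact": factor_exact,
                               "rounded": factor_rounded}
        before = _band_labels(base_pred.to_numpy()[g], bands)
        after = _band_labels(recal[g], bands)
        mat = reclassification_matrix(before, after)
        block["reclassification_group"] = mat.to_dict()
        block["reclassification_group_row_pct"] = mat.attrs["row_pct"].to_dict()
        block["deaths_by_decile_group"] = deaths_by_decile(recal, y, g).tolist()
        out["models"]["normal_x_f"] = block

    refit_specs = {
        "derived": ModelSpec("grace"),
        "derived+smoking": ModelSpec("grace+smoking"),
        "derived+group": ModelSpec("grace+copd"),
    }
    for name, spec in refit_specs.items():
        if name not in config.models:
            continue
        pred, fit, dropped = predict_cohort_model(cohort, spec)
        logger.info("stage=refit model=%s n_used=%d n_dropped=%d", name, fit.n_used, dropped)
        comparator = derived_pred if name != "derived" else None
        block = _model_block(pred, cohort, group, bands, comparator=comparator)
        block["n_dropped"] = dropped
        block["coefficients"] = fit.coef
        block["standard_errors"] = fit.se
        if name == "derived":
            derived_pred = pred
        if name == "derived+group" and derived_pred is not None:
            common = pred.index.intersection(derived_pred.index)
            y = y_all.loc[common].to_numpy()
            nri, z, p = continuous_nri(derived_pred.loc[common].to_numpy(),
                                       pred.loc[common].to_numpy(), y)
            block["nri_vs_derived"] = {"nri": nri, "z": z, "p": p}
            g = group.loc[common].to_numpy()
            before = _band_labels(derived_pred.loc[common].to_numpy()[g], bands)
            after = _band_labels(pred.loc[common].to_numpy()[g], bands)
            mat = reclassification_matrix(before, after)
            block["reclassification_group"] = mat.to_dict()
            block["reclassification_group_row_pct"] = mat.attrs["row_pct"].to_dict()
            block["deaths_by_decile_group"] = deaths_by_decile(
                pred.loc[common].to_numpy(), y, g).tolist()
        out["models"][name] = block

    return out


def subgroup_comparison(config: RunConfig, group_column: str) -> dict:
    """Decile-adjusted M-H RR for an alternative binary subgroup (e.g. diabetes)."""
    sub_cfg = RunConfig(**{**asdict_shallow(config),
                           "subgroup": group_column,
                           "models": ("normal",),
                           "stratify_by": None})
    report = run_validation(sub_cfg)
    return report["models"]["normal"]["mh"]


def write_report(report: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
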