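#!/usr/bin/env python
"""Multiplicative recalibration of the nomogram score for COPD patients.

Estimates the multiplier as the decile-adjusted M-H RR from the nomogram
predictions, multiplies COPD patients' predicted risks by it, and quantifies
the consequences: the residual adjusted RR, how many COPD patients change
treatment-relevant risk band (the reclassification matrix), and how deaths
distribute across deciles of predicted risk before and after.

Reads   scratch/cohort.csv, scratch/predictions_nomogram.csv
Writes  results/recalibration.json
        results/reclassification_copd.csv
        results/deaths_by_decile.csv
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from grace_recal.cohort import identify_copd, read_cohort
from grace_recal.mh import decile_adjusted_rr
from grace_recal.nomogram import RiskBandConfig
from grace_recal.recalibrate import (
    RecalibrationSpec,
    deaths_by_decile,
    recalibrate,
    reclassification_matrix,
)

ROOT = Path(__file__).resolve().parents[1]


def band_of(risks: np.ndarray, bands: RiskBandConfig) -> np.ndarray:
    return np.where(risks < bands.low_upper, "low",
                    np.where(risks <= bands.moderate_upper, "moderate", "high"))


def main() -> None:
    cohort = read_cohort(ROOT / "scratch" / "cohort.csv").set_index("patient_id")
    pred = pd.read_csv(ROOT / "scratch" / "predictions_nomogram.csv").set_index("patient_id")
    merged = cohort.join(pred[["risk"]], how="inner")
    copd = identify_copd(merged).to_numpy()
    died = merged["died_6m"].astype(bool).to_numpy()
    risks = merged["risk"].to_numpy()
    bands = RiskBandConfig()

    est = decile_adjusted_rr(risks, copd, died)
    print(f"estimated multiplier (M-H RR): {est.rr:.4f}; rounded {round(est.rr, 1)}")

    recal = recalibrate(risks, copd, RecalibrationSpec(multiplier=est.rr))
    after = decile_adjusted_rr(recal, copd, died)
    print(f"adjusted RR after recalibration: {after.rr:.2f} "
          f"(95% CI {after.ci_low:.2f} to {after.ci_high:.2f}), was {est.rr:.2f}")

    mat = reclassification_matrix(band_of(risks[copd], bands),
                                  band_of(recal[copd], bands))
    pct = mat.attrs["row_pct"]
    print("COPD reclassification (row %):")
    print(pct.round(1).to_string())
    print(f"low->moderate: {pct.loc['low', 'moderate']:.1f}% of low-risk COPD "
          f"patients become eligible for more aggressive early treatment")

    shares_before = deaths_by_decile(risks, died, copd)
    shares_after = deaths_by_decile(recal, died, copd)

    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "results" / "recalibration.json").write_text(json.dumps({
        "multiplier_exact": est.rr,
        "multiplier_rounded": round(est.rr, 1),
        "rr_before": est.as_dict(),
        "rr_after": after.as_dict(),
    }, indent=2))
    out = mat.copy()
    for b in pct.columns:
        out[f"{b}_row_pct"] = pct[b].round(1)
    out.to_csv(ROOT / "results" / "reclassification_copd.csv")
    pd.DataFrame({
        "decile": range(1, 11),
        "share_of_copd_deaths_normal": shares_before,
        "share_of_copd_deaths_recalibrated": shares_after,
    }).round(4).to_csv(ROOT / "results" / "deaths_by_decile.csv", index=False)
    print("wrote results/recalibration.json and reclassification/deaths tables")


if __name__ == "__main__":
    main()
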