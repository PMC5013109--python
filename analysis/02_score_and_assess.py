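#!/usr/bin/env python
"""Score the cohort with the nomogram and assess subgroup calibration.

Applies the shipped (synthetic stand-in) mini-GRACE nomogram, then asks the
central question: conditional on predicted risk, do COPD patients die more
often?  The decile-adjusted Mantel-Haenszel pooled risk ratio quantifies the
answer; the observed-vs-predicted table by decile and the band-level table
show where the miscalibration sits.

Reads   scratch/cohort.csv  (run 01_simulate_cohort.py first)
Writes  scratch/predictions_nomogram.csv
        results/mh_normal_score.json
        results/observed_vs_predicted_by_decile.csv
        results/observed_by_band.csv
"""

import json
from pathlib import Path

from grace_recal.cohort import identify_copd, read_cohort
from grace_recal.mh import decile_adjusted_rr, observed_by_band, observed_vs_predicted_by_decile
from grace_recal.nomogram import default_nomogram, predict_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort = read_cohort(ROOT / "scratch" / "cohort.csv")
    pred, dropped = predict_cohort(cohort, default_nomogram())
    print(f"scored {len(pred)} records ({dropped} missing a GRACE input)")

    copd = identify_copd(cohort).loc[pred.index].to_numpy()
    died = cohort.loc[pred.index, "died_6m"].astype(bool).to_numpy()
    risks = pred["risk"].to_numpy()
    print(f"mean predicted risk: non-COPD {100 * risks[~copd].mean():.1f}%, "
          f"COPD {100 * risks[copd].mean():.1f}%")

    res = decile_adjusted_rr(risks, copd, died)
    print(f"M-H pooled RR adjusted for predicted-risk deciles: "
          f"{res.rr:.2f} (95% CI {res.ci_low:.2f} to {res.ci_high:.2f})")
    if res.ci_low > 1:
        print("-> the score underestimates risk of death for COPD patients")

    by_decile = observed_vs_predicted_by_decile(risks, died, copd)
    by_band = observed_by_band(risks, died, copd)

    pred.assign(patient_id=cohort.loc[pred.index, "patient_id"]).to_csv(
        ROOT / "scratch" / "predictions_nomogram.csv", index=False)
    (ROOT / "results" / "mh_normal_score.json").write_text(
        json.dumps(res.as_dict(), indent=2))
    by_decile.round(4).to_csv(ROOT / "results" / "observed_vs_predicted_by_decile.csv",
                           index=False)
    by_band.round(4).to_csv(ROOT / "results" / "observed_by_band.csv",
                           index=False)
    print("wrote results tables")


if __name__ == "__main__":
    main()
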