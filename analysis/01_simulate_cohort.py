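#!/usr/bin/env python
"""Simulate the study cohort.

Generates a registry-like ACS cohort (n = 100,000, seed 2016) with the default
group-conditional covariate structure and a COPD log-odds offset of 0.5,
applies the eligibility exclusions, and summarises patient characteristics by
COPD status (the cohort-characteristics table).

Writes
    scratch/cohort.csv                  full cohort (large; scratch only)
    results/cohort_characteristics.csv  group-conditional covariate summary
"""

from pathlib import Path

import pandas as pd

from grace_recal.cohort import apply_exclusions, identify_copd, write_cohort
from grace_recal.synthetic import GeneratorConfig, generate_cohort

ROOT = Path(__file__).resolve().parents[1]
N, SEED = 100_000, 2016


def main() -> None:
    cfg = GeneratorConfig(n=N, seed=SEED)
    cohort = generate_cohort(cfg)
    cohort, log = apply_exclusions(cohort)
    print(f"generated {log.n_input} records, retained {log.n_retained} "
          f"({log.total_excluded()} excluded)")

    copd = identify_copd(cohort)
    print(f"COPD: {copd.sum()} ({100 * copd.mean():.1f}%)")
    for label, sub in (("non-COPD", cohort[~copd]), ("COPD", cohort[copd])):
        print(f"{label}: 6-month mortality {100 * sub['died_6m'].mean():.1f}%, "
              f"mean HR {sub['heart_rate'].mean():.1f}, "
              f"diuretics {100 * sub['diuretic_in_hospital'].mean():.1f}%")

    rows = []
    for label, sub in (("non_copd", cohort[~copd]), ("copd", cohort[copd])):
        rows.append({
            "group": label,
            "n": len(sub),
            "mortality_6m_pct": 100 * sub["died_6m"].mean(),
            "mean_age": sub["age"].mean(),
            "mean_heart_rate": sub["heart_rate"].mean(),
            "mean_systolic_bp": sub["systolic_bp"].mean(),
            "mean_creatinine": sub["creatinine"].mean(),
            "diuretic_pct": 100 * sub["diuretic_in_hospital"].mean(),
            "cardiac_arrest_pct": 100 * sub["cardiac_arrest"].mean(),
            "st_deviation_pct": 100 * sub["st_deviation"].mean(),
            "elevated_markers_pct": 100 * sub["elevated_markers"].mean(),
            "diabetes_pct": 100 * sub["diabetes"].mean(),
            "ex_smoker_pct": 100 * (sub["smoking"] == "ex").mean(),
            "current_smoker_pct": 100 * (sub["smoking"] == "current").mean(),
            "nstemi_pct": 100 * (sub["diagnosis"] == "NSTEMI").mean(),
        })

    (ROOT / "scratch").mkdir(exist_ok=True)
    (ROOT / "results").mkdir(exist_ok=True)
    write_cohort(cohort, ROOT / "scratch" / "cohort.csv")
    pd.DataFrame(rows).round(2).to_csv(
        ROOT / "results" / "cohort_characteristics.csv", index=False)
    print(f"wrote scratch/cohort.csv and results/cohort_characteristics.csv")


if __name__ == "__main__":
    main()
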