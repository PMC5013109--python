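# Synthetic mini-GRACE nomogram (stand-in).
#
# This is NOT a transcription of a published GRACE nomogram: it is a synthetic
# point table with the mini-GRACE structure (age, heart rate, systolic BP,
# creatinine as step functions; diuretic-proxy heart failure, cardiac arrest,
# ST deviation and elevated markers as fixed points) whose score-to-risk curve
# is logistic in the total score.  Points were derived from the synthetic
# generator's default outcome coefficients at ~25 points per log-odds unit, so
# scores produced from generated cohorts are approximately calibrated for
# non-COPD patients.  Replace this file with a transcription of a published
# nomogram for use on real data.
name: synthetic-mini-grace
source: "synthetic stand-in derived from grace_recal.synthetic defaults (25 points per log-odds)"

continuous:
  age:
    - {lower: 30, upper: 40, points: 11}
    - {lower: 40, upper: 50, points: 31}
    - {lower: 50, upper: 60, points: 51}
    - {lower: 60, upper: 70, points: 70}
    - {lower: 70, upper: 80, points: 90}
    - {lower: 80, upper: 90, points: 110}
    - {lower: 90, upper: 110, points: 124}
  heart_rate:
    - {lower: 20, upper: 50, points: 4}
    - {lower: 50, upper: 70, points: 16}
    - {lower: 70, upper: 90, points: 26}
    - {lower: 90, upper: 110, points: 37}
    - {lower: 110, upper: 130, points: 47}
    - {lower: 130, upper: 150, points: 57}
    - {lower: 150, upper: 250, points: 67}
  systolic_bp:
    - {lower: 50, upper: 80, points: 65}
    - {lower: 80, upper: 100, points: 55}
    - {lower: 100, upper: 120, points: 48}
    - {lower: 120, upper: 140, points: 40}
    - {lower: 140, upper: 160, points: 32}
    - {lower: 160, upper: 180, points: 24}
    - {lower: 180, upper: 200, points: 16}
    - {lower: 200, upper: 300, points: 8}
  creatinine:
    - {lower: 10, upper: 70, points: 5}
    - {lower: 70, upper: 100, points: 12}
    - {lower: 100, upper: 130, points: 16}
    - {lower: 130, upper: 180, points: 22}
    - {lower: 180, upper: 250, points: 32}
    - {lower: 250, upper: 350, points: 45}
    - {lower: 350, upper: 1500, points: 60}

boolean:
  diuretic_in_hospital: {points: 20}
  cardiac_arrest: {points: 30}
  st_deviation: {points: 10}
  elevated_markers: {points: 13}

# risk = expit(-3.8 + (score - 151.25) / 25), tabulated every 20 points
score_to_risk:
  - {score: 40, risk: 0.0003}
  - {score: 60, risk: 0.0006}
  - {score: 80, risk: 0.0013}
  - {score: 100, risk: 0.0029}
  - {score: 120, risk: 0.0064}
  - {score: 140, risk: 0.0141}
  - {score: 160, risk: 0.0308}
  - {score: 180, risk: 0.0660}
  - {score: 200, risk: 0.1359}
  - {score: 220, risk: 0.2592}
  - {score: 240, risk: 0.4378}
  - {score: 260, risk: 0.6341}
  - {score: 280, risk: 0.7941}
  - {score: 300, risk: 0.8957}
  - {score: 320, risk: 0.9503}
  - {score: 340, risk: 0.9770}
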