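# Methods

## Estimand and procedure

The package asks whether a 6-month post-ACS mortality score is equally well
calibrated in a subgroup (COPD by default) as in the rest of the cohort,
*conditional on predicted risk*. Predictions from the model under assessment
are pooled (both groups together) into deciles; each decile contributes a 2×2
table of death by subgroup status; the Mantel–Haenszel pooled risk ratio
summarises the per-decile risk ratios,

    RR_MH = ( Σₖ aₖ n0ₖ / Nₖ ) / ( Σₖ bₖ n1ₖ / Nₖ ),

and its 95% CI uses the Greenland–Robins variance of log RR_MH,

    var(ln RR) = Σₖ [ (aₖ+bₖ) n1ₖ n0ₖ / Nₖ² − aₖ bₖ / Nₖ ]
                 / ( [Σₖ aₖ n0ₖ/Nₖ] · [Σₖ bₖ n1ₖ/Nₖ] ),

with normal-theory bounds. This variance estimator is a choice — the
stratified-RR literature offers several — made because it is valid under both
sparse-strata and large-strata asymptotics; it is cross-checked in the test
suite against an independent implementation (metafor's `rma.mh`, frozen
values) and the point estimate against statsmodels' `StratifiedTable`.
Deciles are rank-based equal-count bins with ties broken by stable input
order (bin sizes differ by at most one even under heavy ties). Strata with an
empty group contribute nothing to either sum; they are dropped and counted.

Two repairs are implemented. *Respecification*: maximum-likelihood logistic
regression of 6-month death on the eight score inputs (continuous covariates
standardised with fixed reference constants and entered linearly), optionally
plus smoking (ex/current indicators vs never) or the COPD flag; fitting is
IRLS (statsmodels GLM, binomial family) behind the module surface, with a
rank check, convergence reporting, and separation flagged when any
standardised coefficient exceeds 15 in absolute value. *Multiplicative
recalibration*: the subgroup's predicted risks are multiplied by a factor f —
by default the decile-adjusted RR_MH estimated from the same data — capped at
1, and bands are recomputed. With bands at 3% and 6%, any f < 2 cannot move a
low-risk patient straight to high risk (0.03·f < 0.06), and f ≥ 1 never
demotes anyone: these are structural identities, not empirical findings, and
are tested as such.

Model adjudication: C-statistic via the Mann–Whitney construction (ties count
1/2); paired C-statistic comparisons via DeLong structural components
(two-sided normal p); Hosmer–Lemeshow over g = 10 equal-count prediction
groups with df = g − 2 (the fitted-model convention, applied to all models);
continuous NRI with up/down meaning any strict change in predicted risk
(exact ties count as neither; no epsilon band) and a z-statistic from the
multinomial variance of the two net proportions. No multiple-testing
adjustment is applied anywhere; all CIs and p-values are unadjusted, and the
report says so.

## Cohort handling

Eligibility exclusions run in a fixed order (missing identifier, missing
airway-disease indicator, missing smoking history, missing vital status);
each record is counted under the first matching reason, so the exclusion log
reconciles exactly with the retained count. Missing numeric score inputs do
*not* exclude a record at intake: each downstream step is complete-case for
the variables it needs and reports its own drop count. (Whether a registry
analysis should drop such records listwise or per-model is genuinely open;
per-step complete-case is this package's choice and is surfaced in every
output.) COPD is derived, never stored: airway-disease indicator AND smoking
∈ {ex, current}.

## The synthetic cohort generator

The generator emulates a UK ACS registry at the level of group-conditional
marginals: age drawn from five bands (band shares per group), heart rate and
systolic BP normal, creatinine log-normal (right-skewed lab value), binary
rates for in-hospital diuretic use, cardiac arrest, ST deviation, elevated
markers and diabetes, a three-level smoking distribution (COPD patients are
never never-smokers, by construction of the identification rule), and a
STEMI/NSTEMI/UA diagnosis mix. Published group summaries fix most defaults
(e.g. heart rate 80.2±21.9 vs 87.2±23.7 beats/min; diuretics 22.0% vs 32.5%).
Cardiac-arrest prevalence is not reported in those summaries; 5% in both
groups is a documented placeholder. Diabetes prevalence (20%/25%) and its
outcome effect are package choices sized so the diabetes comparator shows a
clearly smaller conditional excess than COPD.

The outcome is one Bernoulli draw per record from a logistic model on the
standardised covariates plus a subgroup offset δ (default 0.5) on the
log-odds scale. Coefficients (per reference SD or per indicator) follow the
usual ordering of ACS risk factors — age dominant (1.10), cardiac arrest
(1.20), the diuretic heart-failure proxy (0.80), elevated markers (0.50),
heart rate (0.45), ST deviation (0.40), creatinine (0.35), systolic BP
(−0.45), diabetes (0.20) — and the intercept (−3.8) is a documented constant
chosen so overall 6-month mortality is ≈12% under the default mix. The same
standardisation constants are used by the design builder, so a logistic refit
on generated data recovers the generator's coefficients and δ directly
(tested at n = 50,000 within ±3 SE, fitting the full truth including the
diabetes term).

What the generator does **not** emulate: joint covariate correlations beyond
group-conditional marginals, informative missingness (injection is MCAR
only), time trends, hospital clustering, or treatment effects. Passing tests
therefore show that the estimators and repairs behave correctly when their
assumptions hold and when the subgroup excess is a clean log-odds offset;
they do not show that a real registry's miscalibration has that form.

## A structural property worth knowing about

Adjusting for *deciles* of predicted risk is coarse: within a decile,
subgroup members sit systematically higher on the risk scale than
non-members whenever the subgroup's prediction distribution is shifted
upward. The decile-adjusted RR of a *perfectly calibrated* model is therefore
slightly above 1, by an amount that grows with the subgroup's total
predicted-risk shift and shrinks with finer strata (with the default δ = 0.5
the shift is ≈0.7 log-odds and the residual is ≈1.04 at 10 bins, ≈1.004 at
50). The one-shot multiplicative repair inherits this residual and adds a
second, smaller one: a constant risk-ratio multiplier cannot exactly undo a
log-odds offset (it under-corrects at low risk and over-corrects at high
risk, ≈1.02 pooled). Both phenomena are visible in the package's own
recovery analyses: the refit-with-COPD model lands near 1.04 and the
recalibrated score near 1.09 rather than exactly 1.00 under the default
generator. At the smaller subgroup shifts typical of real registries
(≈0.2–0.45 log-odds) the residuals are roughly half as large. The estimand
itself — a pooled average over deciles — is what it is; the package reports
it without continuity corrections or finer-stratum substitutes because decile
adjustment is the procedure under study.

## Numerical and edge-case choices

- Band boundaries: low = [0, 3%), moderate = [3%, 6%], high = (6%, 1];
  the published band labels ("<3%", "3–6%", ">6%") leave exact-boundary
  membership open, so the thresholds are config-visible constants.
- Nomogram point tables are step functions over breakpoint intervals; values
  below the first breakpoint score 0 points, values beyond the last interval
  take the last interval's points; the score→risk curve interpolates linearly
  between anchors and clamps to the terminal risks. (Published nomograms give
  ranges, not slopes, and do not state out-of-range handling; clamping is a
  choice.)
- Logistic fitting: deviance-change convergence at 1e-8, max 100 iterations;
  separation threshold |β| > 15 on the standardised scale; bootstrap
  resamples whole records (cases), skipping and counting non-converged or
  degenerate replicates.
- Recalibrated risks are capped at 1.0; real registry risks never approach
  1/f, but the operation must be total.
- The multiplier is reported at full precision and rounded to one decimal;
  both appear in outputs because a deployable rule would ship the rounded
  value.
- The M-H RR is undefined (raised, not NaN) when no stratum has unexposed
  deaths; deaths-by-decile shares are undefined when the group has no deaths.
- Published headline values for this kind of adjusted RR are sometimes
  reported with inconsistent rounding across summary and results sections
  (e.g. 1.29 vs 1.30 for the same quantity); the pipeline sidesteps the
  ambiguity by reporting one full-precision value everywhere.

## Problem sizes

Unit and property tests run on cohorts of 10²–2×10⁴ records; recovery and
acceptance analyses use one shared 5×10⁴-record cohort (the size at which ±3
SE coefficient recovery and the RR-to-unity checks are sharp); the narrative
analysis scripts use 10⁵. The 100-replicate case bootstrap mirrors the
internal-validation convention for this kind of registry model.

## Known limitations

- The shipped nomogram is a synthetic stand-in calibrated to the generator's
  own outcome model; conclusions about any *published* score require
  transcribing its nomogram into the YAML format.
- Only the binary 6-month death outcome is modelled; no survival times, no
  competing risks.
- Multiplicative recalibration is the only score-preserving repair offered;
  logistic intercept/slope recalibration variants are out of scope.
- Multiple imputation of missing score inputs is out of scope; the pipeline
  is complete-case per step by design.
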