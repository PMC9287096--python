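# deprisk

Deprivation-stratified external validation of cardiovascular 10-year risk
scores.

Area-based socioeconomic deprivation is strongly associated with
cardiovascular risk, yet most widely used primary-prevention risk scores do
not include it as a covariate. `deprisk` is a library-plus-analysis project
for quantifying what that omission does to a score's calibration: it scores
a cohort with survival-type risk equations (ASSIGN, SCORE2, the Pooled
Cohort Equations, or any custom equation expressed as a data file),
recalibrates each score's baseline survival to the cohort, and measures
calibration and discrimination within strata of the Scottish Index of
Multiple Deprivation (SIMD). Because the motivating cohort data are
access-restricted, the package ships a synthetic-cohort generator with a
known deprivation effect, so every estimator can be validated against
generative truth.

It is aimed at biostatisticians and epidemiologists who validate or
recalibrate clinical prediction models.

## The model

Each risk score is a sex-specific survival equation

```
risk_10y = 1 − S0(10) ^ exp(lp − c),       lp = Σk βk · termk(x)
```

where `S0(10)` is the 10-year baseline survival, `c` a centering constant
(0 for pre-centered equations such as SCORE2), and each term a product of
transformed covariates (affine, log, indicator), expressed as YAML data
rather than code. Outcomes are composite endpoints over ICD-10 diagnosis
and cause-of-death codes and OPCS-4 procedure codes, score-specific (only
ASSIGN counts, e.g., coronary admissions I20–I25 and revascularisation
procedures; SCORE2's death list carries printed exclusions such as I51.4).

Validation follows standard survival-model practice:

* observed 10-year risk `O` by Kaplan–Meier (Greenwood SE), mean predicted
  risk `P`, ratio `P/O`, and the Z test `(O − P)/SE(O)`;
* decile calibration curves, calibration slope (Cox on the linear
  predictor) and intercept (`cloglog(O) − cloglog(P)`);
* Harrell's C for discrimination;
* recalibration: per sex, replace `S0(10)` by the root of
  `mean_i[1 − S0^exp(lp_i − c)] = O_sex`, always in the whole cohort, never
  within a deprivation stratum;
* sex-specific Cox refits of each score's term structure with SIMD/10 as an
  additional risk factor.

Deprivation strata: SIMD quintiles (Q1 most deprived, cutoffs 33.81 /
20.98 / 13.67 / 7.94) collapsed to group 1 = Q1, group 2 = Q2–Q4,
group 3 = Q5; missing SIMD forms an explicit reported stratum.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
cohort of 15,000 adults (60% female, median age 51, smoking 29% vs 9% and
diabetes 4.2% vs 2.2% across extreme deprivation groups, 6% missing SIMD,
true deprivation log hazard ratio 0.15 per SIMD/10):

```
python analysis/01_simulate_cohort.py      # cohort + coded events -> scratch/cohort/
python analysis/02_score_raw_models.py     # published equations, no recalibration
python analysis/03_recalibrate_and_evaluate.py
python analysis/04_deprivation_refit.py
python analysis/05_residual_deprivation_demo.py
```

Step 03 prints, for example (SCORE2 after whole-cohort recalibration):

```
score2: S0(10) updated female 0.9776 -> 0.9437, male 0.9605 -> 0.9205
  stratum                  n  events  observed  predicted   P/O      p
  all                    14546    924    5.12%     5.12%   1.00  0.998
  group1_most_deprived    1680    172    8.39%     6.21%   0.74  0.002 *
  group2                  7631    483    5.23%     5.14%   0.98  0.745
  group3_least_deprived   4356    211    3.74%     4.72%   1.26  0.001 *
```

Read: after recalibration the score is perfectly calibrated overall by
construction, yet it still *underpredicts* in the most deprived group
(observed 8.39% vs predicted 6.21%, P/O 0.74, p=0.002) and *overpredicts*
in the least deprived (3.74% vs 4.72%, p=0.001), because the cohort's
deprivation gradient in risk is not captured by the score's covariates.
Step 05 makes the mechanism explicit with a matched pair of equations: the
deprivation-aware spec is calibrated in every group, its deprivation-blind
twin reproduces the under/over pattern. Step 04's refits recover the
generative deprivation effect, e.g. ASSIGN-structure male model HR 1.150
(95% CI 1.095–1.208) per 10 SIMD units.

A thin CLI wraps the same pipeline for file-based cohorts
(`deprisk run --cohort cohort.csv --events events.csv --out results/`; also
`simulate`, `score`, `recalibrate`, `evaluate`, `refit`, `demo`).

The packaged coefficient files under `src/deprisk/data/` are editable
transcriptions; verify them against the source publications before any
clinical use.

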