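# Methods

## Risk-equation engine

A risk model is a declarative object: per sex, a list of named terms, a
coefficient per term, a centering constant `c`, and a 10-year baseline
survival `S0(10) ∈ (0, 1)`. Ten-year risk is `1 − S0^exp(lp − c)` with
`lp = Σ β·term`. Each term is a *product of factors*, each factor one of
four transforms of a raw covariate — identity, affine `a·x + b`, natural
log, indicator — which is sufficient to express ASSIGN's linear terms
(including cigarettes/day and SIMD/10), SCORE2's pre-centered terms and
age interactions (e.g. `(age−60)/5 × smoking`), and PCE's log terms,
squared log-age and treatment-split systolic-pressure terms, all as data.
Consequences of this design: corrected coefficients never require code
changes, and the engine can be checked against independent literal
transcriptions of each equation (the test oracles) to 1e−12.

Conventions: SCORE2 is shipped pre-centered (`c = 0`); ASSIGN and PCE carry
centering constants; PCE uses its White coefficient sets and mg/dL
cholesterol (the unit converter multiplies by 38.67); `bp_treated`
defaults to false, since the cohort schema's covariate list has no
antihypertensive-treatment field but PCE requires one. Ages outside a
spec's derivation range are scored without clamping and logged — clamping
would bias calibration in cohorts that extend beyond the derivation
window. Participants missing a required covariate (for ASSIGN, anyone
missing SIMD) are flagged and excluded from that score's analyses, never
silently dropped or imputed to zero.

The shipped ASSIGN coefficient file is a best-effort transcription
assembled from secondary sources; its term structure, centering convention
and baseline-survival form are faithful, but the decimals must be verified
against the source publication before clinical use (stated in the file
itself). This does not affect any test: oracles compare the engine against
the packaged values, and all cohort-level results are driven by the
synthetic generator's own specs.

## Endpoints

Composite outcomes are unions of components, each a code system (ICD-10
diagnosis, ICD-10 cause of death, OPCS-4 procedure) with inclusion ranges,
optional exclusions, and a fatality requirement. Range expressions follow
published-list conventions: bare categories match by prefix (`I21` matches
`I21.4`), dashed ranges are inclusive at the 3-character category level
(`K40-46` = categories K40…K46), subcode expressions match exactly, and
subcode ranges (`R96.0-R96.1`) are confined to one category and do not
match a bare category code. Exclusions must fall inside an inclusion range
of their component (validated at load). One printed tension is reproduced
verbatim rather than resolved: the cardiovascular-death exclusion list of
the SCORE2-type endpoint names I60 and I62 although both appear in its
nonfatal stroke component.

Follow-up is time to first qualifying event; non-endpoint deaths and
administrative end of follow-up censor (the Kaplan–Meier convention that
underlies observed risks). Competing-risks estimators (Aalen–Johansen) are
out of scope and acknowledged as a methodological limitation: KM-based
"observed 10-year risk" overstates absolute risk in the presence of
competing death, identically so for every score being compared.

## Survival primitives

Kaplan–Meier, Cox and Harrell's C are consumed through one surface
(`SurvivalSample`) and computed by lifelines: the product-limit estimate
and Greenwood variance are assembled from `survival_table_from_events`,
Cox fits use `CoxPHFitter` (Efron ties, Newton iterations, SEs from the
inverse observed information, convergence precision 1e−9), concordance
uses `concordance_index` with risks negated (higher risk ⇒ shorter time).
Guard rails added around the backend: constant covariates are rejected by
name; |coef| > 20 is treated as monotone likelihood (perfect separation)
and raised as an error advising a data check; an optional `strata`
argument gives separate baseline hazards (used when pooling sexes, which
carry different baselines in the generator). Offsets are declared in the
sample type but rejected by `fit_cox`: no operation in this pipeline
consumes one and the backend does not expose it.

Greenwood SE is reported on the risk scale (Var(1−S) = Var(S)); decile
plots use the cloglog-transformed CI so intervals stay inside [0, 1],
plain ±1.96·SE elsewhere; both choices are labelled in every report, since
neither the tie-handling method nor the CI transform is dictated by the
validation design itself. When a requested horizon exceeds the last
observed time the estimate is carried forward with a warning and flagged
unsupported, keeping small stratified subgroups usable.

## Recalibration

Per sex, the updated baseline survival solves
`mean_i[1 − S0^exp(lp_i − c)] = O_sex`, with `O_sex` the sex-specific KM
observed 10-year risk in the whole cohort. The mean risk is strictly
decreasing in `S0`, so Brent root-finding on (1e−12, 1−1e−12) finds the
unique root; the residual is checked below 1e−8. This is the minimal
interpretation of "replacing the baseline survival": no extra parameters,
and it exactly removes whole-cohort over- or underestimation. With all
linear predictors equal to `c` it reduces to the closed form
`S0 = 1 − O`. Recalibration is deliberately never done within deprivation
strata — residual within-stratum miscalibration after whole-cohort
recalibration is precisely the quantity of interest. Per-sex (rather than
pooled) updating was a genuinely open choice; it is flagged in outputs.

## Calibration and discrimination battery

For the whole cohort and each deprivation group: `O` (KM, cloglog 95% CI),
`P` (mean predicted, treated as fixed — no sampling uncertainty attributed
to the predictions), ratio `P/O` (printed with both `O` and `P`, so the
label convention loses no information), `Z = (O − P)/SE_Greenwood(O)` with
a two-sided normal p-value and a 0.05 significance flag, Harrell's C,
decile table (stable-order ties, bin sizes differing by ≤1), calibration
slope (coefficient of lp as sole Cox covariate; 1 under correct relative
risks) and intercept (`cloglog(O) − cloglog(P)`; 0 under correct level,
negative when overpredicting). Slope and intercept estimators are named in
every report because "calibration intercept and slope" admits several
conventions. No multiplicity adjustment is applied across strata or
scores. Zero-event strata are reported with `O = 0`, an undefined ratio
and a warning (Z falls back to a rule-of-three SE), never dropped.

The deprivation refit re-evaluates a spec's own term matrix on the cohort
per sex and appends `simd_per10 = SIMD/10` when no term already uses SIMD
(ASSIGN-structure refits keep their existing deprivation term).
Non-deprivation terms that are constant in the cohort (e.g. the
treatment-split pressure term when nobody is treated) are dropped with a
warning; a constant deprivation column is an error.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are fixed and the
tests assume them. It emulates a population-based adult cohort with a
deprivation gradient: n = 15,000; 60% female; age truncated-normal
(mean 51, sd 10, range 30–75); SIMD drawn as a quintile mixture with
probabilities (0.124, 0.185, 0.185, 0.185, 0.3215) — the deficit of the
most deprived quintile and excess of the least deprived reflect the
healthy-volunteer response bias such cohorts show — then uniform within
quintile bounds, except a right-skewed Beta(1, 3) inside the open-ended
most-deprived quintile. Quintile-conditional covariates target the
documented gradients: current smoking (30.1% … 8.5% from most to least
deprived), diabetes (4.0% … 2.0%), small systolic-pressure shifts, a
family-history gradient; cholesterol and HDL are sex- and age-indexed
normals. Prevalence values between the two documented extremes, and all
distributional shapes, are plausible interpolations chosen once and
documented as not derived from any published table.

Event times follow a Weibull proportional-hazards model (shape 1.3, so
slope/intercept checks exercise a non-constant hazard while inverse
transform sampling stays closed-form) with true log hazard ratios per
covariate, including 0.15 per SIMD/10 for deprivation; sex-specific scales
(female 134, male 96 years) were set so the 10-year composite risk is
≈5.5% in women and ≈8.8% in men — a broad-composite event rate, sitting
inside the generator's 2–12% sanity gate. Censoring: staggered
administrative end of follow-up uniform on 10.5–15.5 years (5-year
recruitment window, >10 years minimum follow-up), exponential dropout
(0.008/yr), and competing non-cardiovascular death (0.004/yr at the
reference age, log HR 0.07 per year of age). Events are emitted as coded
records — fatal causes of death (including R96 sudden death, which the
broad I00–I99 death list does not capture but the SCORE2-type list does),
nonfatal diagnoses, OPCS-4 procedures, plus non-qualifying I10 admissions
as noise — so the endpoint classifier is exercised realistically.
Missingness is injected last (MCAR: SIMD 6%, lipids and pressure 1%),
keeping the ground-truth sidecar complete and complete-case analyses
unbiased by construction; SIMD itself is never imputed.

Two auxiliary generators serve the calibration checks: one draws outcomes
whose event probability by the horizon equals each participant's predicted
risk exactly (Bernoulli event, uniform event time — the perfect-calibration
null for the Z test), and one simulates from a risk-model spec itself,
anchoring a Weibull-shaped cumulative baseline hazard to the spec's
S0(10) so the spec is the true model and the Cox slope of lp is 1 in truth.
`study_spec` exports the generative model as a risk-model spec with or
without the deprivation term: the matched aware/blind pair behind the
demo scenario.

What the generator does not emulate — and hence what passing tests cannot
show about real data: family/relatedness structure, informative (non-MCAR)
missingness, measurement error in covariates, secular trends in event
rates, miscoding of diagnoses, and deprivation pathways outside the single
linear SIMD/10 hazard term.

## Problem sizes and numerical choices

Test and acceptance problem sizes were chosen by power analysis so that
each band is several standard errors wide at the stated n: self-consistency
at n = 50,000 (slope SE ≈ 0.02 against a ±0.05 band), deprivation-effect
recovery at n = 20,000 (SE ≈ 0.026 against ±0.03), direction-of-
miscalibration over 50 replicates of n = 15,000 (per-group |Z| ≈ 3–5), the
Z-test null over 1,000 cohorts of n = 2,000 (≈100 events each), null CI
coverage over 100 replicates of n = 5,000, and full per-term log-HR
recovery at n = 100,000 with sex-stratified baselines (low-prevalence
covariates such as diabetes need that many events for a ±0.14 check).
Root-finding tolerances are 1e−15 (xtol/rtol) with a 1e−8 closure check;
Cox convergence precision 1e−9; scoring is pure and row-order invariant;
all simulation randomness flows from a single integer seed through
`numpy.random.default_rng`.

## Known limitations

KM-based observed risk treats competing death as censoring (see above);
chained-equations multiple imputation is out of scope (a clearly labelled
mean/mode single-imputation flag exists, default off, and never touches
SIMD); SCORE2's regional recalibration scale factors are not applied (the
cohort-level recalibration module subsumes their purpose here); the
rheumatoid-arthritis field is carried in the cohort schema but referenced
by no packaged score; postcode-to-SIMD lookup and SIMD vintage
reconciliation are reader concerns outside the package.
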