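# ASSIGN-style risk equation: linear terms over raw covariates, including
# cigarettes/day, family history and the deprivation covariate SIMD/10. The
# only widely used score of the three that carries deprivation. Coefficient
# values are a best-effort transcription assembled from secondary sources of
# the published equation; the term structure, centering-constant convention
# and 10-year baseline survival form are faithful to the original, but the
# decimals MUST be verified against the source publication before any
# clinical use. Participants with missing SIMD are unscorable by this model
# and are flagged by the engine.
model_name: assign
endpoint: assign_cvd
units:
  cholesterol: mmol/L
valid_age_range: [30, 74]

female:
  terms: &assign_terms
    - name: age
      factors: [{covariate: age, transform: identity}]
    - name: total_chol
      factors: [{covariate: total_chol, transform: identity}]
    - name: hdl_chol
      factors: [{covariate: hdl_chol, transform: identity}]
    - name: systolic_bp
      factors: [{covariate: systolic_bp, transform: identity}]
    - name: cigarettes_per_day
      factors: [{covariate: cigarettes_per_day, transform: identity}]
    - name: diabetes
      factors: [{covariate: diabetes, transform: indicator}]
    - name: family_history_cvd
      factors: [{covariate: family_history_cvd, transform: indicator}]
    - name: simd_per10                # SIMD score divided by 10
      factors: [{covariate: simd, transform: affine, a: 0.1, b: 0.0}]
  coefficients:
    age: 0.07203
    total_chol: 0.12720
    hdl_chol: -0.52360
    systolic_bp: 0.01064
    cigarettes_per_day: 0.02486
    diabetes: 0.88450
    family_history_cvd: 0.47750
    simd_per10: 0.09386
  centering_constant: 4.90
  baseline_survival_10y: 0.9365

male:
  terms: *assign_terms
  coefficients:
    age: 0.05698
    total_chol: 0.15580
    hdl_chol: -0.43470
    systolic_bp: 0.00954
    cigarettes_per_day: 0.02005
    diabetes: 0.66780
    family_history_cvd: 0.27500
    simd_per10: 0.06296
  centering_constant: 4.61
  baseline_survival_10y: 0.8831
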