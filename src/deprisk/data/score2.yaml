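# SCORE2 (uncalibrated model), transcribed from the original publication's
# supplementary coefficient tables. The equation is pre-centered: every
# continuous term is an affine transform of the raw covariate (e.g. cage =
# (age - 60) / 5), so the centering constant is 0. No regional recalibration
# scale factors are applied; cohort-level recalibration is handled by the
# recalibration module. Verify coefficients against the source publication
# before any clinical use.
model_name: score2
endpoint: score2_cvd
units:
  cholesterol: mmol/L
valid_age_range: [40, 69]

female:
  terms: &score2_terms
    - name: cage                     # (age - 60) / 5
      factors: [{covariate: age, transform: affine, a: 0.2, b: -12.0}]
    - name: smoking
      factors: [{covariate: smoker, transform: indicator}]
    - name: csbp                     # (sbp - 120) / 20
      factors: [{covariate: systolic_bp, transform: affine, a: 0.05, b: -6.0}]
    - name: diabetes
      factors: [{covariate: diabetes, transform: indicator}]
    - name: ctchol                   # total cholesterol - 6 mmol/L
      factors: [{covariate: total_chol, transform: affine, a: 1.0, b: -6.0}]
    - name: chdl                     # (HDL - 1.3) / 0.5
      factors: [{covariate: hdl_chol, transform: affine, a: 2.0, b: -2.6}]
    - name: smoking_x_cage
      factors:
        - {covariate: smoker, transform: indicator}
        - {covariate: age, transform: affine, a: 0.2, b: -12.0}
    - name: csbp_x_cage
      factors:
        - {covariate: systolic_bp, transform: affine, a: 0.05, b: -6.0}
        - {covariate: age, transform: affine, a: 0.2, b: -12.0}
    - name: ctchol_x_cage
      factors:
        - {covariate: total_chol, transform: affine, a: 1.0, b: -6.0}
        - {covariate: age, transform: affine, a: 0.2, b: -12.0}
    - name: chdl_x_cage
      factors:
        - {covariate: hdl_chol, transform: affine, a: 2.0, b: -2.6}
        - {covariate: age, transform: affine, a: 0.2, b: -12.0}
    - name: diabetes_x_cage
      factors:
        - {covariate: diabetes, transform: indicator}
        - {covariate: age, transform: affine, a: 0.2, b: -12.0}
  coefficients:
    cage: 0.4648
    smoking: 0.7744
    csbp: 0.3131
    diabetes: 0.8096
    ctchol: 0.1002
    chdl: -0.2606
    smoking_x_cage: -0.1088
    csbp_x_cage: -0.0277
    ctchol_x_cage: -0.0226
    chdl_x_cage: 0.0613
    diabetes_x_cage: -0.1272
  centering_constant: 0.0
  baseline_survival_10y: 0.9776

male:
  terms: *score2_terms
  coefficients:
    cage: 0.3742
    smoking: 0.6012
    csbp: 0.2777
    diabetes: 0.6457
    ctchol: 0.1458
    chdl: -0.2698
    smoking_x_cage: -0.0755
    csbp_x_cage: -0.0255
    ctchol_x_cage: -0.0281
    chdl_x_cage: 0.0426
    diabetes_x_cage: -0.0983
  centering_constant: 0.0
  baseline_survival_10y: 0.9605
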