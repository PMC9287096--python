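# Pooled Cohort Equations (2013 ACC/AHA), White coefficient sets only (the
# validation cohort is predominantly of White background). Cholesterol is in
# mg/dL: the pipeline converts mmol/L cohorts before scoring. The centering
# constant is the derivation cohort's mean linear predictor; risk is
# 1 - S0 ** exp(lp - c). Verify coefficients against the source publication
# before any clinical use.
model_name: pce
endpoint: pce_ascvd
units:
  cholesterol: mg/dL
valid_age_range: [40, 79]

female:
  terms:
    - name: ln_age
      factors: [{covariate: age, transform: log}]
    - name: ln_age_sq
      factors:
        - {covariate: age, transform: log}
        - {covariate: age, transform: log}
    - name: ln_tc
      factors: [{covariate: total_chol, transform: log}]
    - name: ln_age_x_ln_tc
      factors:
        - {covariate: age, transform: log}
        - {covariate: total_chol, transform: log}
    - name: ln_hdl
      factors: [{covariate: hdl_chol, transform: log}]
    - name: ln_age_x_ln_hdl
      factors:
        - {covariate: age, transform: log}
        - {covariate: hdl_chol, transform: log}
    - name: ln_sbp_treated
      factors:
        - {covariate: systolic_bp, transform: log}
        - {covariate: bp_treated, transform: indicator, equals: true}
    - name: ln_sbp_untreated
      factors:
        - {covariate: systolic_bp, transform: log}
        - {covariate: bp_treated, transform: indicator, equals: false}
    - name: smoker
      factors: [{covariate: smoker, transform: indicator}]
    - name: ln_age_x_smoker
      factors:
        - {covariate: age, transform: log}
        - {covariate: smoker, transform: indicator}
    - name: diabetes
      factors: [{covariate: diabetes, transform: indicator}]
  coefficients:
    ln_age: -29.799
    ln_age_sq: 4.884
    ln_tc: 13.540
    ln_age_x_ln_tc: -3.114
    ln_hdl: -13.578
    ln_age_x_ln_hdl: 3.149
    ln_sbp_treated: 2.019
    ln_sbp_untreated: 1.957
    smoker: 7.574
    ln_age_x_smoker: -1.665
    diabetes: 0.661
  centering_constant: -29.18
  baseline_survival_10y: 0.9665

male:
  terms:
    - name: ln_age
      factors: [{covariate: age, transform: log}]
    - name: ln_tc
      factors: [{covariate: total_chol, transform: log}]
    - name: ln_age_x_ln_tc
      factors:
        - {covariate: age, transform: log}
        - {covariate: total_chol, transform: log}
    - name: ln_hdl
      factors: [{covariate: hdl_chol, transform: log}]
    - name: ln_age_x_ln_hdl
      factors:
        - {covariate: age, transform: log}
        - {covariate: hdl_chol, transform: log}
    - name: ln_sbp_treated
      factors:
        - {covariate: systolic_bp, transform: log}
        - {covariate: bp_treated, transform: indicator, equals: true}
    - name: ln_sbp_untreated
      factors:
        - {covariate: systolic_bp, transform: log}
        - {covariate: bp_treated, transform: indicator, equals: false}
    - name: smoker
      factors: [{covariate: smoker, transform: indicator}]
    - name: ln_age_x_smoker
      factors:
        - {covariate: age, transform: log}
        - {covariate: smoker, transform: indicator}
    - name: diabetes
      factors: [{covariate: diabetes, transform: indicator}]
  coefficients:
    ln_age: 12.344
    ln_tc: 11.853
    ln_age_x_ln_tc: -2.664
    ln_hdl: -7.990
    ln_age_x_ln_hdl: 1.769
    ln_sbp_treated: 1.797
    ln_sbp_untreated: 1.764
    smoker: 7.837
    ln_age_x_smoker: -1.795
    diabetes: 0.658
  centering_constant: 61.18
  baseline_survival_10y: 0.9144
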