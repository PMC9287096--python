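# Composite cardiovascular endpoints per risk score, as ICD-10 / OPCS-4
# inclusion ranges (exclusions listed where the published definition states
# them). Dashed ranges are inclusive at the 3-character category level.
# Note: the cardiovascular-death exclusion list of the SCORE2 endpoint names
# I60 and I62 even though both also appear in its nonfatal stroke component;
# the printed lists are reproduced verbatim rather than harmonised.

assign_cvd:
  components:
    - code_system: icd10_cause_of_death     # cardiovascular death
      include: [I00-I99]
      fatal: "yes"
    - code_system: icd10_diagnosis          # coronary disease hospitalisation
      include: [I20-I25]
      fatal: "no"
    - code_system: icd10_diagnosis          # stroke / TIA
      include: [G45, I60-I69]
      fatal: "no"
    - code_system: opcs4_procedure          # revascularisation procedures
      include: [L29.5, L31.1, K40-46, K49, K75]
      fatal: "no"

score2_cvd:
  components:
    - code_system: icd10_cause_of_death     # cardiovascular death
      include: [I10-I16, I20-I25, I46-I52, I60-I69, I70-I73, R96.0-R96.1]
      exclude: [I51.4, I60, I62, I67.1, I68.2, I67.5]
      fatal: "yes"
    - code_system: icd10_diagnosis          # nonfatal stroke
      include: [G45, I60-I69]
      fatal: "no"
    - code_system: icd10_diagnosis          # nonfatal myocardial infarction
      include: [I21-I22]
      fatal: "no"

pce_ascvd:
  components:
    - code_system: icd10_diagnosis          # nonfatal myocardial infarction
      include: [I21-I22]
      fatal: "no"
    - code_system: icd10_cause_of_death     # fatal coronary heart disease
      include: [I20-I25]
      fatal: "yes"
    - code_system: icd10_diagnosis          # nonfatal stroke
      include: [G45, I60-I69]
      fatal: "no"
    - code_system: icd10_cause_of_death     # fatal stroke
      include: [G45, I60-I69]
      fatal: "yes"
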