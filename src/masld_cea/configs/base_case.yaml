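whtr_positivity: 0.226
whtr_stage1_sensitivity: 1.0
discount_rate: 0.03
horizon_years: 10
cohort_size: 100000
program_duration_years: null
blood_panel_all_whtr_positive: true
wtp_thresholds:
- 30584.0
- 71415.5
initial_stage_distribution:
- 0.885
- 0.052
- 0.035
- 0.016
- 0.012
prevalence_by_age:
  6: 0.05000000000000001
  7: 0.053939729289562505
  8: 0.058170879550730185
  9: 0.06271192963464954
  10: 0.06758203512598109
  11: 0.07280096915005271
  12: 0.0783890458806743
  13: 0.08436702474443276
  14: 0.09075599333010907
tests:
  ultrasound:
    sensitivity:
      mean: 0.52
      ci:
      - 0.41
      - 0.64
      dist: beta
    specificity:
      mean: 0.96
      ci:
      - 0.91
      - 0.99
      dist: beta
  fibroscan:
    sensitivity:
      mean: 0.72
      ci:
      - 0.64
      - 0.79
      dist: beta
    specificity:
      mean: 0.98
      ci:
      - 0.97
      - 0.98
      dist: beta
  mri_pdff:
    sensitivity:
      mean: 0.95
      ci:
      - 0.92
      - 0.97
      dist: beta
    specificity:
      mean: 0.92
      ci:
      - 0.77
      - 0.98
      dist: beta
costs:
  routine_exam: 2.9
  ultrasound: 16.5
  fibroscan: 13.0
  mri_pdff: 87.0
  blood_panel: 22.5
  program_fixed_annual: 10.5
  program_variable_annual: 21.7
utilities:
  f0:
    mean: 0.95
    ci:
    - 0.93
    - 1.0
    dist: beta
  f1_f2:
    mean: 0.85
    ci:
    - 0.79
    - 0.92
    dist: beta
  f3:
    mean: 0.73
    ci:
    - 0.64
    - 0.82
    dist: beta
  f4:
    mean: 0.66
    ci:
    - 0.49
    - 0.83
    dist: beta
transitions:
  regression: 0.06
  treated_regression: 0.277
  response_rate: 0.4
  advanced_response_multiplier: 0.75
  boys:
    f0_to_f1:
      mean: 0.004
      ci:
      - 0.002
      - 0.006
      dist: beta
    f1_to_f2:
      mean: 0.033
      ci:
      - 0.02
      - 0.051
      dist: beta
    f2_to_f3:
      mean: 0.033
      ci:
      - 0.02
      - 0.051
      dist: beta
    f3_to_f4:
      mean: 0.034
      ci:
      - 0.019
      - 0.064
      dist: beta
  girls:
    f0_to_f1:
      mean: 0.003
      ci:
      - 0.002
      - 0.005
      dist: beta
    f1_to_f2:
      mean: 0.028
      ci:
      - 0.016
      - 0.043
      dist: beta
    f2_to_f3:
      mean: 0.028
      ci:
      - 0.016
      - 0.043
      dist: beta
    f3_to_f4:
      mean: 0.028
      ci:
      - 0.016
      - 0.054
      dist: beta
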