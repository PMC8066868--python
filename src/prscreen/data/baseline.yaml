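# Canonical input parameter set for the Singapore breast-cancer screening
# cost-effectiveness model. All values are annual probabilities, SGD costs,
# or utility weights. Sources: national incidence/mortality statistics and
# local cost studies (see docs/methods.md).
asir:
  # age_low, age_high (both inclusive), annual incidence probability
  bands:
    - [35, 39, 0.000617]
    - [40, 44, 0.001114]
    - [45, 49, 0.001733]
    - [50, 54, 0.001775]
    - [55, 59, 0.002073]
    - [60, 64, 0.002119]
    - [65, 69, 0.002056]
    - [70, 74, 0.002063]
    - [75, 79, 0.001974]
    - [80, 84, 0.001710]
    - [85, 120, 0.001530]

stage_distribution:
  screened:
    I: 0.53
    II: 0.43
    III: 0.03
    IV: 0.01
  unscreened:
    I: 0.22
    II: 0.57
    III: 0.12
    IV: 0.09

mortality:
  # annual breast-cancer death probability by stage
  stage:
    I: 0.020
    II: 0.044
    III: 0.083
    IV: 0.268
  all_cause: 0.002896

utilities:
  Healthy: 1.000
  I: 0.731
  II: 0.731
  III: 0.599
  IV: 0.352

costs:
  # one-off direct medical cost attached to the diseased state (SGD);
  # accrual convention (per state-year vs once at diagnosis) is a model
  # config choice, see ModelConfig.stage_cost_mode
  stage:
    I: 63983.00
    II: 78226.00
    III: 91129.00
    IV: 110136.00
  test:
    mammogram: 110.00
    ultrasound: 230.00
    self_exam: 0.00
    buccal_swab: 210.00
    questionnaire: 2.00

risk_stratification:
  # PRS percentile cut-offs with the observed Asian-population proportions
  groups:
    - name: low
      percentile_low: 0
      percentile_high: 60
      population_proportion: 0.51
      risk_multiplier: 0.5
    - name: intermediate
      percentile_low: 60
      percentile_high: 95
      population_proportion: 0.41
      risk_multiplier: 1.0
    - name: high
      percentile_low: 95
      percentile_high: 100
      population_proportion: 0.08
      risk_multiplier: 2.0

config:
  start_age: 35
  end_age: 74
  cycle_length: 1
  discount_rate: 0.03
  mammography_sensitivity: 0.8
  detection_mode: screen_plus_preentry
  stage_cost_mode: annual
  half_cycle_correction: false

# Published one-way sensitivity ranges where a table printed explicit
# minima/maxima (costs +/-30%, utilities). Parameters without an entry
# here fall back to the 80%/120% rule at load time. The stage II utility
# maximum is reconstructed as 0.83 (mirroring stage I); the printed range
# collapses to the minimum, which is inconsistent with the stated rule.
osa_bounds:
  stage_cost.I: [44788.10, 83177.90]
  stage_cost.II: [54758.20, 101693.80]
  stage_cost.III: [63790.30, 118467.70]
  stage_cost.IV: [77095.20, 143175.80]
  test_cost.buccal_swab: [122.50, 227.50]
  test_cost.mammogram: [87.50, 162.50]
  test_cost.ultrasound: [161.00, 299.00]
  test_cost.questionnaire: [1.40, 2.60]
  utility.I: [0.63, 0.83]
  utility.II: [0.63, 0.83]
  utility.III: [0.499, 0.599]
  utility.IV: [0.252, 0.452]
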