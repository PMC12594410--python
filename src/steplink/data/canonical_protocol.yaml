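steps:
- step_id: '1'
  stratification: surgery_death
  claims_pool: visit_only
  gate_granularity_birth: MONTH
  variables:
  - id: 1
    granularity: MONTH
  - id: 2
    granularity: null
  - id: 3
    granularity: DAY
  - id: 4
    granularity: DAY
  - id: 5
    granularity: MONTH
  - id: 6
    granularity: DAY
  - id: 7
    granularity: DAY
  acceptance:
    kind: min_score
    threshold: 4
    min_dates: 2
    max_adjusted: null
- step_id: 1.A
  stratification: surgery_death
  claims_pool: visit_only
  gate_granularity_birth: MONTH
  variables:
  - id: 1
    granularity: MONTH
  - id: 2
    granularity: null
  - id: 3
    granularity: DAY
  - id: 4
    granularity: DAY
  - id: 5
    granularity: MONTH
  - id: 6
    granularity: MONTH
  - id: 7
    granularity: DAY
  acceptance:
    kind: min_score
    threshold: 4
    min_dates: 2
    max_adjusted: null
- step_id: 1.B
  stratification: surgery_death
  claims_pool: visit_only
  gate_granularity_birth: MONTH
  variables:
  - id: 1
    granularity: MONTH
  - id: 2
    granularity: null
  - id: 3
    granularity: DAY
  - id: 4
    granularity: DAY
  - id: 5
    granularity: MONTH
  - id: 6
    granularity: DAY
  - id: 7
    granularity: MONTH
  acceptance:
    kind: min_score
    threshold: 4
    min_dates: 2
    max_adjusted: null
- step_id: '2'
  stratification: sex_chemo
  claims_pool: visit_only
  gate_granularity_birth: MONTH
  variables:
  - id: 1
    granularity: MONTH
  - id: 2
    granularity: null
  - id: 3
    granularity: DAY
  - id: 4
    granularity: DAY
  - id: 9
    granularity: DAY
  acceptance:
    kind: min_score_or_dates
    threshold: 4
    min_dates: 2
    max_adjusted: null
- step_id: '3'
  stratification: sex_radio
  claims_pool: visit_only
  gate_granularity_birth: MONTH
  variables:
  - id: 1
    granularity: MONTH
  - id: 2
    granularity: null
  - id: 3
    granularity: DAY
  - id: 4
    granularity: DAY
  - id: 10
    granularity: DAY
  acceptance:
    kind: min_score_or_dates
    threshold: 4
    min_dates: 2
    max_adjusted: null
- step_id: '4'
  stratification: endoscopy
  claims_pool: visit_only
  gate_granularity_birth: MONTH
  variables:
  - id: 1
    granularity: MONTH
  - id: 2
    granularity: null
  - id: 3
    granularity: DAY
  - id: 4
    granularity: DAY
  - id: 11
    granularity: DAY
  acceptance:
    kind: min_score
    threshold: 4
    min_dates: 2
    max_adjusted: null
- step_id: 5-strict
  stratification: null
  claims_pool: visit_or_stay
  gate_granularity_birth: YEAR
  variables:
  - id: 1
    granularity: YEAR
  - id: 2
    granularity: null
  - id: 3
    granularity: DAY
  - id: 4
    granularity: DAY
  - id: 5
    granularity: MONTH
  - id: 6
    granularity: DAY
  - id: 7
    granularity: DAY
  - id: 9
    granularity: DAY
  - id: 10
    granularity: DAY
  - id: 11
    granularity: DAY
  acceptance:
    kind: min_score
    threshold: 4
    min_dates: 2
    max_adjusted: 0
- step_id: 5-adjusted
  stratification: null
  claims_pool: visit_or_stay
  gate_granularity_birth: YEAR
  variables:
  - id: 1
    granularity: YEAR
  - id: 2
    granularity: null
  - id: 3
    granularity: DAY
  - id: 4
    granularity: DAY
  - id: 5
    granularity: MONTH
  - id: 6
    granularity: DAY
  - id: 7
    granularity: DAY
  - id: 9
    granularity: DAY
  - id: 10
    granularity: DAY
  - id: 11
    granularity: DAY
  acceptance:
    kind: min_score
    threshold: 4
    min_dates: 2
    max_adjusted: 1
- step_id: 6-strict
  stratification: null
  claims_pool: visit_or_stay
  gate_granularity_birth: YEAR
  variables:
  - id: 1
    granularity: YEAR
  - id: 2
    granularity: null
  - id: 3
    granularity: MONTH
  - id: 4
    granularity: MONTH
  - id: 5
    granularity: MONTH
  - id: 6
    granularity: MONTH
  - id: 7
    granularity: MONTH
  - id: 9
    granularity: DAY
  - id: 10
    granularity: DAY
  - id: 11
    granularity: DAY
  acceptance:
    kind: min_score
    threshold: 4
    min_dates: 2
    max_adjusted: 0
- step_id: 6-adjusted
  stratification: null
  claims_pool: visit_or_stay
  gate_granularity_birth: YEAR
  variables:
  - id: 1
    granularity: YEAR
  - id: 2
    granularity: null
  - id: 3
    granularity: MONTH
  - id: 4
    granularity: MONTH
  - id: 5
    granularity: MONTH
  - id: 6
    granularity: MONTH
  - id: 7
    granularity: MONTH
  - id: 9
    granularity: DAY
  - id: 10
    granularity: DAY
  - id: 11
    granularity: DAY
  acceptance:
    kind: min_score
    threshold: 4
    min_dates: 2
    max_adjusted: 1
- step_id: 7-s9
  stratification: null
  claims_pool: visit_or_stay
  gate_granularity_birth: null
  variables:
  - id: 1
    granularity: YEAR
  - id: 2
    granularity: null
  - id: 3
    granularity: MONTH
  - id: 4
    granularity: MONTH
  - id: 5
    granularity: MONTH
  - id: 6
    granularity: MONTH
  - id: 7
    granularity: MONTH
  - id: 9
    granularity: DAY
  - id: 10
    granularity: DAY
  - id: 11
    granularity: DAY
  acceptance:
    kind: exact_score
    threshold: 9
    min_dates: 2
    max_adjusted: null
- step_id: 7-s7
  stratification: null
  claims_pool: visit_or_stay
  gate_granularity_birth: null
  variables:
  - id: 1
    granularity: YEAR
  - id: 2
    granularity: null
  - id: 3
    granularity: MONTH
  - id: 4
    granularity: MONTH
  - id: 5
    granularity: MONTH
  - id: 6
    granularity: MONTH
  - id: 7
    granularity: MONTH
  - id: 9
    granularity: DAY
  - id: 10
    granularity: DAY
  - id: 11
    granularity: DAY
  acceptance:
    kind: exact_score
    threshold: 7
    min_dates: 2
    max_adjusted: null
- step_id: 7-s6
  stratification: null
  claims_pool: visit_or_stay
  gate_granularity_birth: null
  variables:
  - id: 1
    granularity: YEAR
  - id: 2
    granularity: null
  - id: 3
    granularity: MONTH
  - id: 4
    granularity: MONTH
  - id: 5
    granularity: MONTH
  - id: 6
    granularity: MONTH
  - id: 7
    granularity: MONTH
  - id: 9
    granularity: DAY
  - id: 10
    granularity: DAY
  - id: 11
    granularity: DAY
  acceptance:
    kind: exact_score
    threshold: 6
    min_dates: 2
    max_adjusted: null
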