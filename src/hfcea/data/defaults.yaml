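# Default model inputs: Chinese HFrEF cost-utility model of add-on SGLT2 inhibition.
# Per-cycle probabilities are quarterly (3-month cycles); monetary values in 2020 USD
# (converted from CNY at 6.44 CNY/USD); utilities are per-cycle QALY weights.
arms:
  dapagliflozin:
    cv_death_per_cycle: 0.01650
    hosp_per_cycle: 0.01668
    drug_cost_per_cycle: 60.93
  control1:
    cv_death_per_cycle: 0.01994
    hosp_per_cycle: 0.02344
    drug_cost_per_cycle: 0.0
  empagliflozin:
    cv_death_per_cycle: 0.01956
    hosp_per_cycle: 0.02619
    drug_cost_per_cycle: 59.25
  control2:
    cv_death_per_cycle: 0.02120
    hosp_per_cycle: 0.03719
    drug_cost_per_cycle: 0.0

readmit_per_hosp: 0.1189

costs:
  standard_per_cycle: 118.95
  hosp_per_event: 1785.36

# Quarterly NYHA class transition probabilities among survivors (rows: from I..IV).
nyha_matrix:
  - [0.977, 0.019, 0.004, 0.0]
  - [0.008, 0.981, 0.010, 0.001]
  - [0.0, 0.034, 0.960, 0.006]
  - [0.0, 0.0, 0.055, 0.945]

# Age-specific non-cardiovascular death probability per cycle (national cause-of-death
# statistics); upper bounds exclusive; the last band is carried forward for older ages.
noncv_mortality:
  - {age_low: 65, age_high: 70, prob: 0.002430}
  - {age_low: 70, age_high: 75, prob: 0.003042}
  - {age_low: 75, age_high: 80, prob: 0.004185}

utilities:
  NYHA1: 0.2035
  NYHA2: 0.18
  NYHA3: 0.1475
  NYHA4: 0.127
  event_disutility: -0.1

settings:
  start_age: 66.0
  cycle_length_years: 0.25
  horizon_years: 10.0
  annual_discount: 0.05
  wtp_per_qaly: 11008.07
  gdp_per_capita: 11008.07
  initial_distribution: [0.0, 0.713, 0.28, 0.007]
  half_cycle_correction: true
  discount_convention: mid_cycle   # or start_of_cycle
  # One-off hospitalization/readmission QALY decrements enter undiscounted by
  # default; set true to discount them like the per-cycle state utilities.
  discount_event_disutility: false
  noncv_mortality_is_annual: false
  sample_nyha_matrix: true         # include NYHA rows in the PSA
  dirichlet_concentration: 1000.0

# Uncertain-parameter declarations for OWSA and PSA: range interpreted as a 95% CI
# when fitting Beta/Gamma distributions (method of moments, sd = span / (2 * 1.96)).
parameter_specs:
  - {path: arms.dapagliflozin.cv_death_per_cycle, low: 0.01485, high: 0.01815, distribution: beta}
  - {path: arms.control1.cv_death_per_cycle, low: 0.01795, high: 0.02193, distribution: beta}
  - {path: arms.empagliflozin.cv_death_per_cycle, low: 0.01760, high: 0.02152, distribution: beta}
  - {path: arms.control2.cv_death_per_cycle, low: 0.01908, high: 0.02332, distribution: beta}
  - {path: arms.dapagliflozin.hosp_per_cycle, low: 0.01500, high: 0.01835, distribution: beta}
  - {path: arms.control1.hosp_per_cycle, low: 0.02110, high: 0.02578, distribution: beta}
  - {path: arms.empagliflozin.hosp_per_cycle, low: 0.02357, high: 0.02881, distribution: beta}
  - {path: arms.control2.hosp_per_cycle, low: 0.03347, high: 0.04091, distribution: beta}
  - {path: readmit_per_hosp, low: 0.10701, high: 0.13079, distribution: beta}
  - {path: utilities.NYHA1, low: 0.19525, high: 0.21250, distribution: beta}
  - {path: utilities.NYHA2, low: 0.17325, high: 0.18725, distribution: beta}
  - {path: utilities.NYHA3, low: 0.13775, high: 0.15725, distribution: beta}
  - {path: utilities.NYHA4, low: 0.10300, high: 0.15125, distribution: beta}
  - {path: utilities.event_disutility, low: -0.13, high: -0.08, distribution: beta}
  - {path: costs.standard_per_cycle, low: 118.95, high: 556.21, distribution: gamma}
  - {path: arms.dapagliflozin.drug_cost_per_cycle, low: 48.74, high: 73.12, distribution: gamma}
  - {path: arms.empagliflozin.drug_cost_per_cycle, low: 47.40, high: 71.10, distribution: gamma}
  - {path: costs.hosp_per_event, low: 964.07, high: 3209.47, distribution: gamma}
  - {path: settings.annual_discount, low: 0.0, high: 0.08, distribution: fixed}
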