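# Base-case scenario: annual Argentine birth cohort under 6 months (2019),
# suspected cow's-milk-protein-allergy pathway, 24-month horizon, 2024 USD.
demographics:
  population_under_6mo: 312721
  ebf_fraction: 0.42
  mixed_fraction: 0.46
  suspected_incidence: 0.068
  confirmed_incidence: 0.02
  mixed_formula_share: 1.0
clinical:
  ehf_effectiveness: 0.90
  aaf_effectiveness: 1.00
  tolerance_cumulative:
    12: 0.56
    24: 0.77
  diagnostic_duration_weeks: 4
  challenge_interval_months: 6
  tolerance_exit: exit_model
costs:
  monthly_cost:
    AAF: {young: 1426.0, old: 739.0}
    eHF: {young: 1170.0, old: 673.0}
  age_band_switch_months: 9.0
  diagnostic_pricing: published
time:
  entry_age_months: 3.0
  horizon_age_months: 24.0
  days_per_month: 30.4375
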