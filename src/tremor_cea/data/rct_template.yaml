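# Template for an alternative-inputs run (e.g. effectiveness taken from a
# different clinical trial).  Replace every `null` with a value; the loader
# rejects unfilled templates.  Costs are GBP per year unless noted.
settings:
  discount_rate: 0.035
  horizon_years: 5
  cycle_years: 1
  start_age: 70
  male_fraction: 0.46
  wtp_grid: {start: 0, stop: 100000, step: 1000}
  population_size: 1415

# Omit to use the bundled synthetic England-style schedule.
# life_table: my_life_table.csv

strategies:
  mrgfus:
    p_marked: null
    p_mild: null
    p_none: null
    waning_annual: null
    recurrence_annual: null
    p_reop_given_recurrence: 0.05
    onset_delay_fraction: 0.0
    procedure_cost: 16500
    bundle_years: 5
    monitoring_annual: {1: 0, 6: 169}
    medication_annual: 744
    u_bt: null
    u_tr: null
    u_mt_y1: null
    u_mt_y2plus: null
    u_mmt_y1: null
    u_mmt_y2plus: null
    ae_costs: {}
  dbs:
    p_marked: null
    p_mild: null
    p_none: null
    waning_annual: null
    recurrence_annual: null
    p_reop_given_recurrence: 0.05
    onset_delay_fraction: 0.25
    procedure_cost: 47627
    bundle_years: 1
    monitoring_annual: {1: 0, 2: 3172}
    medication_annual: 744
    u_bt: null
    u_tr: null
    u_mt_y1: null
    u_mt_y2plus: null
    u_mmt_y1: null
    u_mmt_y2plus: null
    ae_costs: {}
  none:
    p_marked: 0.0
    p_mild: 0.0
    p_none: 1.0
    waning_annual: 0.0
    recurrence_annual: 0.0
    p_reop_given_recurrence: 0.0
    onset_delay_fraction: 0.0
    procedure_cost: 0
    bundle_years: 0
    monitoring_annual: {1: 169}
    medication_annual: 744
    u_bt: null
    u_tr: null
    u_mt_y1: null
    u_mt_y2plus: null
    u_mmt_y1: null
    u_mmt_y2plus: null
    ae_costs: {}

psa:
  n_iterations: 1000
  sd_fraction: 0.2
  marked_counts: null
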