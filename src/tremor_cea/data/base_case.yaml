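# Base-case parameterisation: unilateral MRgFUS vs unilateral DBS vs
# medication-only care for medically refractory essential tremor, NHS
# England perspective, 2019 GBP, cohort starting at age 70.
settings:
  discount_rate: 0.035
  horizon_years: 5
  cycle_years: 1
  start_age: 70
  male_fraction: 0.46
  wtp_grid: {start: 0, stop: 100000, step: 1000}
  population_size: 1415

life_table: life_table_england_synthetic.csv

strategies:
  mrgfus:
    p_marked: 0.889          # marked improvement (50-100% CRST reduction)
    p_mild: 0.100            # mild/moderate improvement (10-50%)
    p_none: 0.011            # unsuccessful (<10%), remains at baseline
    waning_annual: 0.092     # annual MT -> MMT waning of benefit
    recurrence_annual: 0.01
    p_reop_given_recurrence: 0.05
    onset_delay_fraction: 0.0    # benefit is immediate
    procedure_cost: 16500        # tariff bundles 5 years of follow-up
    bundle_years: 5
    monitoring_annual: {1: 0, 6: 169}
    medication_annual: 744
    u_bt: 0.69
    u_tr: 0.69               # recurrence assumed as disabling as baseline
    u_mt_y1: 0.91
    u_mt_y2plus: 0.90
    u_mmt_y1: 0.80
    u_mmt_y2plus: 0.79
    ae_costs:                # retained for sensitivity analysis; no
      infection: 657         # base-case cash flow (AEs handled within
      intracranial_haemorrhage: 20545   # routine follow-up)
      lead_fracture_or_migration: 14777
      gait_disturbance: 0
      speech_problem: 42
  dbs:
    p_marked: 0.889
    p_mild: 0.100
    p_none: 0.011
    waning_annual: 0.077
    recurrence_annual: 0.039
    p_reop_given_recurrence: 0.05
    onset_delay_fraction: 0.25   # ~3 months of stimulator optimisation
    procedure_cost: 47627        # tariff bundles the first year of follow-up
    bundle_years: 1
    monitoring_annual: {1: 0, 2: 3172}
    medication_annual: 744
    u_bt: 0.69
    u_tr: 0.69
    u_mt_y1: 0.91
    u_mt_y2plus: 0.91
    u_mmt_y1: 0.80
    u_mmt_y2plus: 0.76
    ae_costs:
      infection: 657
      intracranial_haemorrhage: 20545
      lead_fracture_or_migration: 14777
      gait_disturbance: 0
      speech_problem: 42
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
    u_bt: 0.69
    u_tr: 0.69
    u_mt_y1: 0.69            # unused: no cohort fraction ever improves
    u_mt_y2plus: 0.69
    u_mmt_y1: 0.69
    u_mmt_y2plus: 0.69
    ae_costs: {}

# Probabilistic sensitivity analysis defaults: proportions/probabilities and
# utilities sampled from beta, costs from gamma, by moment matching; the
# marked-improvement proportion takes its spread from the Wilson interval of
# the 8/9 trial arm, everything else from an SD of 20% of the mean.
psa:
  n_iterations: 1000
  sd_fraction: 0.2
  marked_counts: {successes: 8, n: 9}

dsa:
  pm_fraction: 0.2
  report_threshold: 0.05
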