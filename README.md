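# tremor-cea

A Markov cohort cost-effectiveness model of unilateral magnetic
resonance-guided focused ultrasound (MRgFUS) against unilateral deep brain
stimulation (DBS) and against medication-only care for medically refractory
essential tremor (mrET), from the perspective of NHS England in 2019 GBP.

The package is aimed at health-economics analysts: it reproduces a published
England cost-utility analysis at desk scale and makes every input — clinical
effectiveness, costs, utilities, the mortality schedule — a configurable,
validated parameter, so the same machinery can be re-run on other tariffs,
trial results or populations.

## The model

A cohort enters immediately post-procedure, split across five health states:

* **BT** — baseline (disabling) tremor: untreated patients and failed
  procedures (<10% improvement on the Clinical Rating Scale for Tremor),
* **MMT** — mild-to-moderately improved (10–50%),
* **MT** — markedly improved (50–100%),
* **TR** — tremor recurrence awaiting re-operation (transient, one cycle),
* **DEAD** — absorbing.

Cycles are one year over a 5-year horizon. Within a cycle, competing risks
nest as mortality → recurrence → waning: every alive state dies with the
age- and sex-blended all-cause probability `q(a)`; survivors in MT or MMT
recur with the strategy's annual recurrence probability (a 5% share of
recurrences proceeds to re-operation via TR, which re-applies the primary
outcome distribution next cycle and is charged the procedure tariff; the
rest fall back to BT); surviving non-recurrent MT patients wane to MMT.

Per-patient totals at discount rate *r* = 3.5% are

```
C = c_proc + Σ_{t=1..T} (1+r)^-t [ alive_t · (c_med + c_mon(t)) + tr_t · c_proc ]
Q =          Σ_{t=1..T} (1+r)^-t   x_{t-1} · u(t)
```

with occupancy rows `x_t`, adverse-event-adjusted utilities `u(t)` that
switch from year-1 to year-2+ values after the first cycle (DBS additionally
spends the first quarter of year 1 at baseline utility while the stimulator
is optimised), and strategies compared by the incremental cost-effectiveness
ratio ICER = ΔC/ΔQ or declared dominant when ΔC < 0 and ΔQ > 0.

Uncertainty handling: one-way sensitivity analysis over 95% Wilson intervals
(trial proportions) or ±20% ranges with a >5% reporting filter; Monte Carlo
probabilistic sensitivity analysis (beta for probabilities and utilities,
gamma for costs, shared parameters drawn once per iteration) summarised as
cost-effectiveness acceptability curves; and scenario analyses over starting
age, horizon, a blended "current care" comparator, no discounting, and
wholesale alternative input files.

## Worked example

```sh
$ tremor-cea run -o results/
Strategy Cost (£) Δ Cost (£) QALY Δ QALY      ICER (£/QALY)
  mrgfus   19,582            3.70
     dbs   61,050    -41,468 3.62   0.08 mrgfus is dominant
    none    3,741     15,840 2.93   0.77             20,669
```

Reading the table: over five years a focused-ultrasound patient costs
£19,582 and accrues 3.70 QALYs. Against DBS, MRgFUS is *dominant* — £41,468
cheaper and 0.08 QALYs better — so no ICER is quoted. Against medication
alone it costs £15,840 more for 0.77 extra QALYs, an ICER of £20,669 per
QALY, inside the £20,000–30,000 per QALY range NICE conventionally accepts.
Machine-precision CSVs (results table, per-cycle cohort traces, a
reproducibility manifest) land in `results/`.

Other subcommands: `tremor-cea dsa` (tornado tables), `psa`
(1,000-iteration Monte Carlo + CEACs, seeded), `ceac --wtp 0:100000:1000`,
`scenario -s start_age --age 40` (likewise `horizon`, `current_care`,
`no_discount`, `alternative_inputs`), and `synth` (random valid configs for
pipeline testing). The same operations are available as library functions
(`tremor_cea.evaluate_all`, `tremor_cea.sensitivity.run_psa`, ...).

All-cause mortality is a model input (CSV with `age,q_male,q_female`); the
bundled schedule is a synthetic Gompertz table calibrated for the bundled
base case — substitute a national life table via the `life_table:` config
key for other settings. See `docs/methods.md` for conventions, parameter
provenance and limitations.

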