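# Methods

This note records the model's assumptions, the conventions we fixed where
the source analysis left them open, the provenance of every default, and
what the test suite does and does not establish.

## Model structure

A five-state Markov cohort model (BT, MMT, MT, TR, DEAD) with one-year
cycles and a default five-year horizon. The cohort enters immediately
post-procedure at the outcome split (88.9% marked improvement, 10.0%
mild/moderate, 1.1% unsuccessful for both procedures; the medication-only
cohort starts entirely at baseline). TR is transient: any fraction entering
it redistributes over the primary outcome split one cycle later, on the
assumption that a re-operation behaves like the first operation.

Competing risks within a cycle nest in a fixed precedence — all-cause
mortality first, then recurrence, then waning — which keeps transition rows
stochastic by construction. The source analysis does not state its
ordering; this is the conventional nesting, and at the base-case rates
(recurrence ≤ 3.9%/yr, waning ≤ 9.2%/yr, q ≤ 5%/yr) the ordering ambiguity
is second-order (products of small probabilities).

Patients whose recurrence does not lead to re-operation return to BT and
stay there: the published state diagram shows no path back to surgery for
them, so no re-treatment is modelled. Age advances one integer year per
cycle for the mortality lookup.

## Accrual and discounting conventions

The published analysis was built in a spreadsheet and prints neither its
discounting convention, its half-cycle handling, nor its mortality rates —
only the resulting totals. We therefore fixed the conventions once, by
calibrating against the printed per-patient totals, and they are not
runtime options:

* cycle-`t` flows are discounted by `(1+r)^-t`; the procedure tariff is
  charged at `t = 0` undiscounted;
* recurring costs (medication, monitoring, re-operation) accrue on the
  **end-of-cycle** occupancy row — those who die during a year do not
  generate that year's recurring costs;
* QALYs accrue on the **start-of-cycle** occupancy row — those alive at
  the start of a year contribute that year's utility;
* no half-cycle correction.

The mixed convention is the only end/start combination under which the
published medication-only totals (£3,735 and 2.95 QALYs) are jointly
reachable: they imply different effective survival annuities (≈4.09
cost-side vs ≈4.28 QALY-side), which a single accrual row cannot produce.
It also reproduces the published MRgFUS QALY total more closely than
end-of-cycle QALYs do. The cost of the convention is a mild asymmetry:
decedents accrue a full year of utility but no recurring cost in their
final year.

## Mortality input

All-cause mortality enters as a life table (`age,q_male,q_female`), blended
with a male fraction of 0.46 at age 70 (the published analysis cites
national statistics without printing a value). The bundled table —
`life_table_england_synthetic.csv` — is **synthetic**: a Gompertz schedule
(blended q(70) = 0.029, hazard growth 1.10/yr, male/female hazard ratio
≈1.55) spanning ages 40–85, calibrated once so the bundled base case lands
on the published totals. It is deliberately heavier than current England
national life tables (blended q(70) ≈ 0.015): the published medication-only
cost of £3,735 cannot be reproduced under contemporary rates, which put it
near £3,990. Users studying other populations should substitute a real
national life table via the `life_table:` config key; the headline
incremental results are only mildly mortality-sensitive (the vs-medication
ICER moves by roughly 5% between the synthetic schedule and a
contemporary-rate table).

## Base-case parameters

All defaults ship in `data/base_case.yaml` (2019 GBP):

| Parameter | Value | Notes |
|---|---|---|
| Outcome split (both procedures) | 88.9 / 10.0 / 1.1 % | English trial arm (8/9 marked), Wilson-augmented |
| Waning MT→MMT | 9.2 %/yr MRgFUS, 7.7 %/yr DBS | annual probabilities |
| Recurrence | 1.0 %/yr MRgFUS, 3.9 %/yr DBS | from MT and MMT |
| Re-operation given recurrence | 5 % | expert assumption |
| Procedure tariff | £16,500 MRgFUS (bundles 5 y follow-up), £47,627 DBS (bundles 1 y) | |
| Monitoring | £169/yr untreated and MRgFUS yr 6+; £3,172/yr DBS yr 2+ | zero inside bundles |
| Medication | £744/yr, all alive states, all strategies | tremor persists in the untreated arm |
| Utilities | BT 0.69; MT 0.91→0.90 (MRgFUS) / 0.91→0.91 (DBS); MMT 0.80→0.79 / 0.80→0.76 | AE-adjusted year-1 → year-2+ |
| TR utility | = BT | recurrence as disabling as baseline |
| DBS onset delay | 3 months (0.25 of year 1 at BT utility) | stimulator optimisation |
| Discount rate | 3.5 %/yr | costs and QALYs |
| Adverse-event tariffs | £0–£20,545 | carried for sensitivity analysis; **zero base-case flow** |

Adverse events influence the base case only through the utility
adjustments: the MRgFUS tariff explicitly absorbs AE management in routine
follow-up, and the per-event DBS incidence needed to cash-flow the AE
tariffs is not in the main publication. The printed DBS total exceeds our
procedure+monitoring+medication reconstruction by ≈£1,200 (≈2%), which may
be exactly such an unrecoverable AE flow; we report the reconstruction
rather than invent an incidence.

## Sensitivity analyses

**One-way (tornado).** Each parameter path moves to the bounds of its
range — the 95% Wilson score interval for the trial-arm proportion
(8/9 → 0.565–0.980), otherwise ±20% of base — clipped to its legal domain,
holding all else fixed. Rows are reported when either bound moves an ICER
by more than 5% (the published filter), ordered by bound-to-bound span with
alphabetical tie-breaks. Varying the shared outcome proportion rescales the
mild/unsuccessful remainder proportionally so the simplex is preserved.

**Probabilistic.** 1,000 Monte Carlo iterations; probabilities and
utilities are beta, costs gamma, parameterised by moment matching with
sd = Wilson-implied (trial proportion) or 20% of the mean. The published
text assigns distributions to "probabilities" and "cost parameters" only;
sampling utilities as beta is our choice. Parameters shared by the
strategies are drawn once per iteration. For utilities we share the
*no-adverse-event anchors* (baseline 0.69 and marked 0.91, with the
mild/moderate anchor their midpoint, mirroring how its base value was set)
and shift each strategy's AE-adjusted values by their base-case offsets:
sampling the per-strategy utilities independently instead would make the
MRgFUS-vs-DBS QALY difference change sign in a third of iterations,
flatly contradicting the published finding that MRgFUS was the more
cost-effective strategy in every iteration. Iteration `i` draws from a
counter-derived substream `SeedSequence((seed, i))`, so results are
bit-reproducible and iteration `i` is invariant to the total count.

Per-iteration ICERs are summarised through acceptability curves and
incremental scatter, not by averaging ratios (ratio averages are dominated
by near-zero QALY differences); the published "average ICER" values are
therefore not reproduced here.

## Scenarios

Starting age changes only the mortality slice; horizon re-runs with the
band-based monitoring schedule extending past the bundle; the no-discount
scenario sets r = 0. The current-care comparator mixes the DBS and
no-procedure *results*: cost and QALYs are exactly linear in the eligible
fraction f. The published blend table is in fact not linear — its printed
costs sit above the linear mix of its own printed endpoints by
≈ 1,325·f(1−f) GBP (and QALYs below by ≈ 0.146·f(1−f)), a symmetric
quadratic signature of some unstated cohort-level mixing. Result-level
mixing reproduces the published blend ICER at f = 0.10 within 2% but
overshoots the hyper-sensitive f = 0.20 value (small ΔC denominator...
small ΔC numerator) by ≈9%; the corresponding check in the acceptance
suite is knowingly failing, and the dominance threshold (f = 0.30) and
linearity property hold.

## Numerical choices and degenerate inputs

Probability simplex tolerance 1e-9 at load; trace conservation holds to
1e-12 and is asserted in tests. ΔQ = 0 comparisons yield an explicit
"undefined ICER" outcome, not an exception. Beta moment matching rejects
sd² ≥ m(1−m); sd = 0 (and means of exactly 0 or 1) degenerate to point
masses, which is what makes the zero-variance PSA reproduce the
deterministic base case bit-for-bit. Wilson bounds at k = 0 and k = n are
returned as exact 0 and 1 (their analytic values) rather than
floating-point residue. Currency and QALY rounding happens only in the
pretty report; CSVs carry full precision.

## What the tests show — and don't

The suite (≈160 tests, seconds of runtime) checks the engine against an
independent path-enumeration oracle for horizons ≤ 3, closed forms in the
zero-discount/zero-mortality limit, conservation and monotone-death
invariants under 200 fuzzed parameter sets, the Wilson formula against an
independent implementation, and the published headline numbers at ±5%
(deterministic) and ±5 percentage points (PSA fractions, at 1,000
iterations). Problem sizes are the study's own: a five-state cohort, 5–10
year horizons, 1,000 PSA iterations.

Synthetic inputs (random parameter sets, Gompertz life tables) exercise
validation and invariants; they do not emulate real covariance between
clinical parameters, real tariff structures, or non-Gompertz old-age
mortality, so passing tests establish internal correctness of the model
arithmetic, not external validity of any particular parameterisation.

## Known limitations

* Cohort (aggregate) model only; no patient-level simulation.
* No lifetime extrapolation: effectiveness data beyond 5 years is absent,
  and the published analysis declined it for the same reason.
* Healthcare-payer perspective only: no carer, productivity or battery
  replacement costs.
* The DBS adverse-event cash flow and the exact current-care mixing rule
  of the source analysis are not recoverable from the main text (see
  above); both discrepancies are quantified and documented rather than
  patched over.
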