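"""Discounted cost and QALY accrual over a cohort trace, and ICERs.

Accounting conventions (deliberate, documented in the methods note):

* Cycles are one year; cash flows and QALYs for cycle ``t`` are discounted
  by ``(1 + r)**-t`` (end-of-cycle discounting, no half-cycle correction).
* The procedure tariff is charged once at ``t = 0``, undiscounted.
* Recurring costs (medication for everyone, monitoring per the strategy's
  year-band schedule) accrue on the *end-of-cycle* occupancy: patients who
  die during a cycle do not generate that cycle's recurring costs.
* QALYs accrue on the *start-of-cycle* occupancy: patients alive at the
  start of a year contribute that year's utility.  First-cycle utilities
  use the year-1 (adverse-event-adjusted) values, blended with baseline
  utility for the onset-delay fraction of the year; later cycles use the
  year-2+ values.
* A cohort fraction occupying TR at the end of cycle ``t`` is charged the
  procedure tariff (its re-operation) in that cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import BT, DEAD, MMT, MT, TR, CohortTrace, run_cohort
from .parameters import (
    EconSettings,
    LifeTable,
    ModelInputs,
    StrategyInputs,
    StrategyName,
    ValidationError,
)

__all__ = [
    "StrategyResult",
    "Comparison",
    "discount_factor",
    "cycle_cost",
    "cycle_qaly",
    "evaluate_strategy",
    "evaluate_all",
    "compare",
    "net_monetary_benefit",
    "comparison_table",
    "DOMINANT",
    "DOMINATED",
    "UNDEFINED",
]

DOMINANT = "intervention dominant"
DOMINATED = "intervention dominated"
UNDEFINED = "undefined ICER"


@dataclass(frozen=True)
class StrategyResult:
    """Discounted per-patient totals for one strategy, with provenance."""

    name: StrategyName
    total_cost: float
    total_qaly: float
    per_cycle_costs: np.ndarray
    per_cycle_qalys: np.ndarray
    trace: CohortTrace

    def net_monetary_benefit(self, wtp: float) -> float:
        return net_monetary_benefit(self, wtp)


@dataclass(frozen=True)
class Comparison:
    """Incremental comparison of an intervention against a comparator.

    ``icer`` is ΔC/ΔQ when meaningful; otherwise ``label`` carries the
    classification (dominance when the intervention is cheaper and more
    effective, dominated in the mirror case, undefined when ΔQ = 0).
    """

    intervention: StrategyName
    comparator: StrategyName
    delta_cost: float
    delta_qaly: float
    icer: float | None
    label: str | None

    @property
    def is_dominant(self) -> bool:
        return self.label == DOMINANT

    def describe(self) -> str:
        if self.label == DOMINANT:
            return f"{self.intervention.value} is dominant"
        if self.label == DOMINATED:
            return f"{self.intervention.value} is dominated"
        if self.label == UNDEFINED:
            return "undefined (no QALY difference)"
        return f"{self.icer:,.0f}"


def discount_factor(t: int, r: float) -> float:
    """End-of-cycle discount factor ``(1 + r)**-t`` for cycle ``t >= 1``."""
    if t < 1:
        raise ValidationError(f"discount cycle index must be >= 1, got {t}")
    if r < 0:
        raise ValidationError(f"discount rate must be >= 0, got {r}")
    return float((1.0 + r) ** (-t))


def cycle_cost(row: np.ndarray, reop_flow: float, s: StrategyInputs, year: int) -> float:
    """Undiscounted recurring cost of model year ``year`` (1-based).

    ``alive * (medication + monitoring[band(year)]) + reop_flow * tariff``.
    Medication is charged to every alive state in every strategy; monitoring
    follows the strategy's year-band schedule (zero inside the procedure's
    bundled years).
    """
    alive = float(np.sum(row[:DEAD]))
    recurring = s.medication_annual + s.monitoring_for_year(year)
    return alive * recurring + float(reop_flow) * s.procedure_cost


def cycle_qaly(row: np.ndarray, s: StrategyInputs, year: int) -> float:
    """Undiscounted QALYs accrued in model year ``year`` by occupancy ``row``.

    Improved-state utilities switch from their year-1 to their year-2+
    values after the first cycle; in the first cycle the improved states
    spend ``onset_delay_fraction`` of the year at baseline utility before
    treatment benefit begins.
    """
    if year < 1:
        raise ValidationError(f"cycle index must be >= 1, got {year}")
    if year == 1:
        d = s.onset_delay_fraction
        u_mt = d * s.u_bt + (1.0 - d) * s.u_mt_y1
        u_mmt = d * s.u_bt + (1.0 - d) * s.u_mmt_y1
    else:
        u_mt, u_mmt = s.u_mt_y2plus, s.u_mmt_y2plus
    utilities = np.zeros_like(row)
    utilities[BT] = s.u_bt
    utilities[MMT] = u_mmt
    utilities[MT] = u_mt
    utilities[TR] = s.u_tr
    return float(row @ utilities)


def evaluate_strategy(
    s: StrategyInputs, e: EconSettings, lt: LifeTable
) -> StrategyResult:
    """Run the cohort and accrue discounted totals for one strategy."""
    trace = run_cohort(s, e, lt)
    T = e.horizon_years
    costs = np.zeros(T + 1)
    qalys = np.zeros(T + 1)
    costs[0] = s.procedure_cost if s.is_procedure else 0.0
    for t in range(1, T + 1):
        df = discount_factor(t, e.discount_rate)
        costs[t] = df * cycle_cost(trace.occupancy[t], trace.reop_flow[t], s, t)
        qalys[t] = df * cycle_qaly(trace.occupancy[t - 1], s, t)
    return StrategyResult(
        name=s.name,
        total_cost=float(costs.sum()),
        total_qaly=float(qalys.sum()),
        per_cycle_costs=costs,
        per_cycle_qalys=qalys,
        trace=trace,
    )


def evaluate_all(inputs: ModelInputs) -> dict[StrategyName, StrategyResult]:
    """Evaluate every configured strategy under the same settings."""
    return {
        name: evaluate_strategy(s, inputs.settings, inputs.life_table)
        for name, s in inputs.strategies.items()
    }


def compare(intervention: StrategyResult, comparator: StrategyResult) -> Comparison:
    """Incremental cost, QALYs and ICER (or dominance label)."""
    d_cost = intervention.total_cost - comparator.total_cost
    d_qaly = intervention.total_qaly - comparator.total_qaly
    icer: float | None = None
    label: str | None = None
    if d_qaly == 0.0:
        label = None if d_cost == 0.0 else UNDEFINED
    elif d_cost < 0.0 and d_qaly > 0.0:
        label = DOMINANT
    elif d_cost > 0.0 and d_qaly < 0.0:
        label = DOMINATED
    else:
        icer = d_cost / d_qaly
    return Comparison(
        intervention=intervention.name,
        comparator=comparator.name,
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        icer=icer,
        label=label,
    )


def net_monetary_benefit(result: StrategyResult, wtp: float) -> float:
    """``wtp * QALYs - cost`` at willingness-to-pay ``wtp`` (GBP/QALY)."""
    if wtp < 0:
        raise ValidationError(f"willingness-to-pay must be >= 0, got {wtp}")
    return wtp * result.total_qaly - result.total_cost


def comparison_table(
    results: dict[StrategyName, StrategyResult],
    intervention: StrategyName = StrategyName.MRGFUS,
) -> pd.DataFrame:
    """Base-case results table: one row per strategy, deltas vs the intervention.

    Deltas are intervention-minus-comparator, so a *negative* Δcost with a
    *positive* ΔQALY marks the intervention as dominant over that row's
    strategy.
    """
    rows = []
    inter = results[intervention]
    rows.append(
        {
            "strategy": intervention.value,
            "cost": inter.total_cost,
            "delta_cost": np.nan,
            "qaly": inter.total_qaly,
            "delta_qaly": np.nan,
            "icer": "",
        }
    )
    for name, res in results.items():
        if name is intervention:
            continue
        cmp_ = compare(inter, res)
        rows.append(
            {
                "strategy": name.value,
                "cost": res.total_cost,
                "delta_cost": cmp_.delta_cost,
                "qaly": res.total_qaly,
                "delta_qaly": cmp_.delta_qaly,
                "icer": cmp_.describe(),
            }
        )
    return pd.DataFrame(rows)
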