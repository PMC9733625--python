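"""Scenario analyses: parameterised re-runs of the base model.

Five scenarios are supported: a different cohort starting age (mortality
slice changes, nothing else), a different time horizon, a blended
"current care" comparator (a population mixture of DBS-treated and
untreated patients, mixed at the *result* level so costs and QALYs are
exactly linear in the eligible fraction), no discounting, and a full re-run
on an alternative input file (e.g. parameters taken from a different trial).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economics import (
    DOMINANT,
    DOMINATED,
    StrategyResult,
    compare,
    comparison_table,
    evaluate_all,
)
from .parameters import ModelInputs, StrategyName, ValidationError, load_config
from .sensitivity import PSAResult, PsaSpec, run_dsa, run_psa

__all__ = [
    "ScenarioResult",
    "run_age_scenario",
    "run_horizon_scenario",
    "run_current_care_blend",
    "run_no_discount_scenario",
    "run_alternative_inputs",
    "blend_results",
    "current_care_sweep",
    "AlternativeInputsResult",
]


@dataclass(frozen=True)
class ScenarioResult:
    """A scenario's per-strategy results and its base-case-shaped summary."""

    name: str
    inputs: ModelInputs
    results: dict
    table: pd.DataFrame

    def comparison(self, comparator: StrategyName):
        return compare(self.results[StrategyName.MRGFUS], self.results[comparator])


def _evaluate(name: str, inputs: ModelInputs) -> ScenarioResult:
    results = evaluate_all(inputs)
    return ScenarioResult(name=name, inputs=inputs, results=results,
                          table=comparison_table(results))


def run_age_scenario(inputs: ModelInputs, age: int) -> ScenarioResult:
    """Re-run with the cohort starting at ``age``; only mortality changes."""
    if not inputs.life_table.covers(age, inputs.settings.horizon_years):
        raise ValidationError(
            f"life table does not cover a cohort starting at age {age}"
        )
    return _evaluate(f"start_age={age}", inputs.with_settings(start_age=age))


def run_horizon_scenario(inputs: ModelInputs, horizon_years: int) -> ScenarioResult:
    """Re-run with a ``horizon_years``-year horizon.

    Beyond a procedure's bundled years its year-band monitoring cost applies
    (for MRgFUS, standard monitoring from year 6 when the horizon exceeds 5).
    """
    return _evaluate(
        f"horizon={horizon_years}",
        inputs.with_settings(horizon_years=int(horizon_years)),
    )


def run_no_discount_scenario(inputs: ModelInputs) -> ScenarioResult:
    """Re-run with a zero discount rate; everything else at base."""
    return _evaluate("no_discount", inputs.with_settings(discount_rate=0.0))


def blend_results(
    dbs: StrategyResult, none: StrategyResult, eligible_fraction: float
) -> tuple[float, float]:
    """(cost, QALY) of the current-care mixture at the given DBS-eligible
    fraction: ``f * DBS + (1 - f) * no-procedure`` on the strategy totals."""
    if not (0.0 <= eligible_fraction <= 1.0):
        raise ValidationError("eligible_fraction must lie in [0, 1]")
    f = eligible_fraction
    cost = f * dbs.total_cost + (1.0 - f) * none.total_cost
    qaly = f * dbs.total_qaly + (1.0 - f) * none.total_qaly
    return cost, qaly


def run_current_care_blend(inputs: ModelInputs, eligible_fraction: float) -> pd.DataFrame:
    """Compare MRgFUS with a blended current-care comparator.

    Returns a one-row frame with the blend's cost/QALY, the incremental
    values (MRgFUS minus blend) and the ICER or dominance label.
    """
    res = evaluate_all(inputs)
    return _blend_row(res, eligible_fraction)


def _blend_row(res: dict, f: float) -> pd.DataFrame:
    cost_b, qaly_b = blend_results(res[StrategyName.DBS], res[StrategyName.NONE], f)
    m = res[StrategyName.MRGFUS]
    dc = m.total_cost - cost_b
    dq = m.total_qaly - qaly_b
    if dq == 0.0:
        icer, label = np.nan, ("" if dc == 0.0 else "undefined")
    elif dc < 0.0 and dq > 0.0:
        icer, label = np.nan, DOMINANT
    elif dc > 0.0 and dq < 0.0:
        icer, label = np.nan, DOMINATED
    else:
        icer, label = dc / dq, ""
    return pd.DataFrame(
        [
            {
                "eligible_fraction": f,
                "blend_cost": cost_b,
                "blend_qaly": qaly_b,
                "delta_cost": dc,
                "delta_qaly": dq,
                "icer": icer,
                "label": label,
            }
        ]
    )


def current_care_sweep(
    inputs: ModelInputs, fractions=tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))
) -> pd.DataFrame:
    """The current-care table over a grid of DBS-eligible fractions."""
    res = evaluate_all(inputs)
    return pd.concat([_blend_row(res, float(f)) for f in fractions], ignore_index=True)


@dataclass(frozen=True)
class AlternativeInputsResult:
    """Base-case, one-way and probabilistic analyses on substituted inputs."""

    scenario: ScenarioResult
    dsa: dict
    psa: PSAResult


def run_alternative_inputs(
    path,
    n_iterations: int = 1000,
    seed: int = 42,
    psa_spec: PsaSpec | None = None,
) -> AlternativeInputsResult:
    """Run the full machinery (base case, DSA, PSA) on another config file.

    Intended for validating the model against externally published trial
    inputs; a key-complete template ships with the package
    (``data/rct_template.yaml``).
    """
    inputs = load_config(path)
    scenario = _evaluate(f"alternative_inputs:{path}", inputs)
    dsa = run_dsa(inputs)
    psa = run_psa(inputs, spec=psa_spec, n_iterations=n_iterations, seed=seed)
    return AlternativeInputsResult(scenario=scenario, dsa=dsa, psa=psa)
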