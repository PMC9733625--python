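"""Markov cohort engine: transition matrices and cohort traces.

A cohort enters the model immediately post-procedure (or untreated, for the
medication-only strategy) and is pushed through annual cycles.  Within a
cycle the competing risks are nested in a fixed precedence: all-cause
mortality first, then tremor recurrence, then waning of procedural benefit —
so rows are stochastic by construction.  Recurrence from an improved state
routes a small fraction (``p_reop_given_recurrence``) into the transient TR
state, which resolves in the following cycle by re-applying the primary
outcome distribution (a re-operation behaves like the first procedure);
everyone else with recurrence falls back to baseline tremor and stays there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import (
    EconSettings,
    HealthState,
    LifeTable,
    N_STATES,
    StrategyInputs,
    ValidationError,
    blended_mortality,
)

__all__ = [
    "CohortTrace",
    "initial_distribution",
    "annual_probability",
    "transition_matrix",
    "run_cohort",
]

BT, MMT, MT, TR, DEAD = (int(s) for s in HealthState)


@dataclass(frozen=True)
class CohortTrace:
    """Cycle-by-state occupancy of the simulated cohort.

    ``occupancy`` has ``horizon + 1`` rows; row 0 is the distribution
    immediately post-procedure and row ``t`` the distribution at the end of
    cycle ``t``.  ``reop_flow[t]`` is the cohort fraction occupying TR at the
    end of cycle ``t`` (zero at t = 0); it drives re-operation charges.
    """

    occupancy: np.ndarray
    reop_flow: np.ndarray

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != N_STATES:
            raise ValidationError(f"trace occupancy must be (T+1, {N_STATES})")
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "reop_flow", np.asarray(self.reop_flow, dtype=float))

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def alive(self, t: int) -> float:
        return float(1.0 - self.occupancy[t, DEAD])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.occupancy, columns=[s.name for s in HealthState]
        )
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        df["reop_flow"] = self.reop_flow
        return df


def initial_distribution(s: StrategyInputs) -> np.ndarray:
    """State vector immediately post-procedure.

    Procedures place ``p_marked`` in MT, ``p_mild`` in MMT and ``p_none``
    (unsuccessful, <10% CRST improvement) in BT; the medication-only cohort
    starts fully in BT.
    """
    v = np.zeros(N_STATES)
    if s.is_procedure:
        v[MT] = s.p_marked
        v[MMT] = s.p_mild
        v[BT] = s.p_none
    else:
        v[BT] = 1.0
    return v


def annual_probability(p_cum: float, years: float) -> float:
    """Convert a cumulative probability over ``years`` to an annual one.

    Assumes a constant per-year probability: ``1 - (1 - p_cum)**(1/years)``,
    the inverse of re-compounding over the period.
    """
    if not (0.0 <= p_cum <= 1.0):
        raise ValidationError(f"p_cum must lie in [0, 1], got {p_cum!r}")
    if years <= 0:
        raise ValidationError(f"years must be > 0, got {years!r}")
    if p_cum == 1.0:
        return 1.0
    return float(-np.expm1(np.log1p(-p_cum) / years))


def transition_matrix(s: StrategyInputs, q_death: float) -> np.ndarray:
    """Row-stochastic 5x5 one-cycle transition matrix at death risk ``q_death``.

    Conditional on surviving the cycle: MT recurs with ``recurrence_annual``
    (of which ``p_reop_given_recurrence`` goes to TR and the rest to BT),
    otherwise wanes to MMT with ``waning_annual``, otherwise stays; MMT
    recurs with the same split, otherwise stays; BT stays; TR redistributes
    per the primary outcome distribution (re-operation outcome equals the
    primary outcome); DEAD is absorbing.
    """
    if not (0.0 <= q_death <= 1.0):
        raise ValidationError(f"q_death must lie in [0, 1], got {q_death!r}")
    r, w = s.recurrence_annual, s.waning_annual
    if r + w > 1.0 + 1e-12:
        raise ValidationError(
            f"recurrence_annual + waning_annual must be <= 1 (got {r + w})"
        )
    p_surv = 1.0 - q_death
    reop = s.p_reop_given_recurrence
    m = np.zeros((N_STATES, N_STATES))
    m[:, DEAD] = q_death
    m[DEAD] = 0.0
    m[DEAD, DEAD] = 1.0
    m[BT, BT] = p_surv

    m[MT, TR] = p_surv * r * reop
    m[MT, BT] = p_surv * r * (1.0 - reop)
    m[MT, MMT] = p_surv * (1.0 - r) * w
    m[MT, MT] = p_surv * (1.0 - r) * (1.0 - w)

    m[MMT, TR] = p_surv * r * reop
    m[MMT, BT] = p_surv * r * (1.0 - reop)
    m[MMT, MMT] = p_surv * (1.0 - r)

    init = initial_distribution(s)
    m[TR, :] = p_surv * init
    m[TR, DEAD] = q_death
    return m


def run_cohort(s: StrategyInputs, e: EconSettings, lt: LifeTable) -> CohortTrace:
    """Push the cohort through ``e.horizon_years`` one-year cycles.

    Age advances one integer year per cycle for the mortality lookup; cycle
    ``t`` (1-based) uses the death probability at age ``start_age + t - 1``.
    """
    if not lt.covers(e.start_age, e.horizon_years):
        raise ValidationError(
            f"life table [{lt.age_min}, {lt.age_max}] does not cover ages "
            f"[{e.start_age}, {e.start_age + e.horizon_years - 1}]"
        )
    occ = np.empty((e.horizon_years + 1, N_STATES))
    occ[0] = initial_distribution(s)
    for t in range(1, e.horizon_years + 1):
        q = blended_mortality(lt, e.start_age + t - 1, e.male_fraction)
        occ[t] = occ[t - 1] @ transition_matrix(s, q)
    return CohortTrace(occupancy=occ, reop_flow=occ[:, TR].copy())
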