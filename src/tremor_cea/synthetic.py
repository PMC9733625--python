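"""Generators for synthetic but valid model inputs.

These stand in for the study's data context so every stage of the pipeline
can be exercised without any external file: random strategy parameter sets
that always pass the validators, parametric (Gompertz) life tables in place
of a national mortality schedule, and a degenerate distribution spec under
which the probabilistic analysis reproduces the deterministic base case
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .parameters import LifeTable, StrategyInputs, StrategyName, ValidationError
from .sensitivity import PsaSpec

__all__ = [
    "GeneratorSpec",
    "random_strategy_inputs",
    "gompertz_life_table",
    "fit_gompertz",
    "degenerate_psa_spec",
]

#: Default (low, high) bounds for generated parameters; probabilities and
#: utilities are drawn uniformly, costs log-uniformly.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "waning_annual": (0.0, 0.3),
    "recurrence_annual": (0.0, 0.3),
    "p_reop_given_recurrence": (0.0, 0.5),
    "onset_delay_fraction": (0.0, 0.5),
    "procedure_cost": (1_000.0, 100_000.0),
    "monitoring_annual": (50.0, 5_000.0),
    "medication_annual": (50.0, 5_000.0),
    "u_bt": (0.3, 0.9),
    "u_gap": (0.0, 0.4),  # improved-state utility headroom above baseline
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Bounds and mortality-shape parameters for the generators."""

    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    gompertz_a: float = 3e-5
    gompertz_b: float = 0.095

    def __post_init__(self) -> None:
        merged = {**DEFAULT_BOUNDS, **dict(self.bounds)}
        for key, (lo, hi) in merged.items():
            if not (lo <= hi):
                raise ValidationError(f"bounds[{key}]: low must be <= high")
        object.__setattr__(self, "bounds", merged)
        if self.gompertz_a <= 0 or self.gompertz_b <= 0:
            raise ValidationError("gompertz parameters must be positive")

    def bound(self, key: str) -> tuple[float, float]:
        return self.bounds[key]


def _uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(rng.uniform(lo, hi))


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    if lo <= 0:
        raise ValidationError("log-uniform bounds must be positive")
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def random_strategy_inputs(
    rng: np.random.Generator,
    spec: GeneratorSpec | None = None,
    name: StrategyName = StrategyName.MRGFUS,
) -> StrategyInputs:
    """A random, always-valid parameter set for one treatment strategy.

    The post-procedure outcome proportions are a normalised draw from the
    3-simplex; waning and recurrence are rescaled if their sum exceeds one;
    improved-state utilities sit a random gap above the baseline utility so
    the ordering BT <= MMT <= MT always holds.
    """
    spec = spec or GeneratorSpec()
    if name is StrategyName.NONE:
        raise ValidationError("the medication-only strategy has no random outcomes")
    simplex = rng.dirichlet(np.ones(3))
    waning = _uniform(rng, *spec.bound("waning_annual"))
    recurrence = _uniform(rng, *spec.bound("recurrence_annual"))
    total = waning + recurrence
    if total > 1.0:
        waning, recurrence = waning / total, recurrence / total
    u_bt = _uniform(rng, *spec.bound("u_bt"))
    gap_lo, gap_hi = spec.bound("u_gap")
    u_mt = min(1.0, u_bt + _uniform(rng, gap_lo, gap_hi))
    u_mmt = (u_bt + u_mt) / 2.0
    bundle_years = int(rng.integers(0, 6))
    monitoring = {1: 0.0 if bundle_years >= 1 else _log_uniform(rng, *spec.bound("monitoring_annual"))}
    monitoring[bundle_years + 1] = _log_uniform(rng, *spec.bound("monitoring_annual"))
    return StrategyInputs(
        name=name,
        p_marked=float(simplex[0]),
        p_mild=float(simplex[1]),
        p_none=float(1.0 - simplex[0] - simplex[1]),
        waning_annual=waning,
        recurrence_annual=recurrence,
        p_reop_given_recurrence=_uniform(rng, *spec.bound("p_reop_given_recurrence")),
        onset_delay_fraction=_uniform(rng, *spec.bound("onset_delay_fraction")),
        procedure_cost=_log_uniform(rng, *spec.bound("procedure_cost")),
        bundle_years=bundle_years,
        monitoring_annual=monitoring,
        medication_annual=_log_uniform(rng, *spec.bound("medication_annual")),
        u_bt=u_bt,
        u_tr=u_bt,
        u_mt_y1=u_mt,
        u_mt_y2plus=max(0.0, u_mt - 0.01),
        u_mmt_y1=u_mmt,
        u_mmt_y2plus=max(0.0, u_mmt - 0.01),
    )


def gompertz_life_table(
    a: float, b: float, age_lo: int = 40, age_hi: int = 100,
    sex_ratio: float = 1.25,
) -> LifeTable:
    """A Gompertz-hazard life table: monotone, two parameters, no download.

    The annual death probability integrates the hazard ``a * exp(b * x)``
    over one year of age: ``q(x) = 1 - exp(-a exp(bx) (exp(b) - 1) / b)``,
    clipped to [0, 1].  Male and female hazards are the blend scaled up and
    down by ``sex_ratio``.
    """
    if a <= 0 or b <= 0:
        raise ValidationError("gompertz parameters must be positive")
    if age_lo >= age_hi:
        raise ValidationError("age_lo must be below age_hi")
    ages = np.arange(age_lo, age_hi + 1)
    h = a * np.exp(b * ages) * np.expm1(b) / b
    q_male = 1.0 - np.exp(-np.clip(h * sex_ratio, 0, None))
    q_female = 1.0 - np.exp(-np.clip(h / sex_ratio, 0, None))
    return LifeTable(ages, np.clip(q_male, 0, 1), np.clip(q_female, 0, 1))


def fit_gompertz(age1: int, q1: float, age2: int, q2: float) -> tuple[float, float]:
    """Solve (a, b) so the Gompertz table passes through two (age, q) points."""
    if not (0 < q1 < 1 and 0 < q2 < 1) or age1 == age2:
        raise ValidationError("need two distinct ages with q in (0, 1)")
    h1, h2 = -np.log1p(-q1), -np.log1p(-q2)
    b = float(np.log(h2 / h1) / (age2 - age1))
    if b <= 0:
        raise ValidationError("points imply a non-increasing hazard")
    a = float(h1 * b / (np.exp(b * age1) * np.expm1(b)))
    return a, b


def degenerate_psa_spec() -> PsaSpec:
    """A point-mass distribution spec: sampling returns the base values."""
    return PsaSpec(sd_fraction=0.0, marked_counts=None)
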