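"""Uncertainty analyses: one-way (deterministic) and probabilistic.

The one-way analysis (:func:`run_dsa`) moves each parameter to the bounds of
its assigned range — the 95% Wilson score interval for trial proportions,
otherwise +/-20% of the base value clipped to the parameter's legal domain —
holding everything else fixed, and reports the parameters whose high or low
bound moves an ICER by more than 5% (tornado ordering: widest bound-to-bound
ICER span first).

The probabilistic analysis (:func:`run_psa`) is a Monte Carlo re-evaluation
of the full model: probabilities and utilities are drawn from beta
distributions and costs from gamma distributions, parameterised by moment
matching from (mean = base value, sd = Wilson-implied or 20% of the mean).
Parameters shared by the treatment strategies — the post-procedure outcome
split, the baseline and no-adverse-event improved utilities, medication
cost and the re-operation probability — are drawn once per iteration and
applied to every strategy; strategy-specific parameters are drawn
independently.  Per-iteration incremental cost/QALY pairs feed the
cost-effectiveness acceptability curves (:func:`ceac`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .economics import compare, evaluate_all
from .parameters import (
    ModelInputs,
    StrategyName,
    ValidationError,
    get_param,
    parameter_paths,
    set_param,
)

__all__ = [
    "ParamRange",
    "DsaRow",
    "PsaSpec",
    "PSAResult",
    "CeacCurve",
    "wilson_interval",
    "build_ranges",
    "run_dsa",
    "sample_inputs",
    "run_psa",
    "ceac",
    "COMPARISONS",
]

#: The two incremental comparisons the model reports.
COMPARISONS = {
    "mrgfus_vs_none": (StrategyName.MRGFUS, StrategyName.NONE),
    "mrgfus_vs_dbs": (StrategyName.MRGFUS, StrategyName.DBS),
}


# ---------------------------------------------------------------------------
# Wilson score interval
# ---------------------------------------------------------------------------

def wilson_interval(successes: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Centre ``(p + z^2/2n) / (1 + z^2/n)`` with half-width
    ``z * sqrt(p(1-p)/n + z^2/4n^2) / (1 + z^2/n)``; always inside [0, 1]
    and always containing the point estimate ``successes / n``.
    """
    if n < 1:
        raise ValidationError(f"wilson_interval: n must be >= 1, got {n}")
    if not (0 <= successes <= n):
        raise ValidationError(
            f"wilson_interval: successes must lie in [0, {n}], got {successes}"
        )
    if not (0.0 < confidence < 1.0):
        raise ValidationError("wilson_interval: confidence must lie in (0, 1)")
    z = float(stats.norm.ppf(0.5 + confidence / 2.0))
    p = successes / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n)) / denom
    # at the boundaries centre -/+ half is exactly 0 or 1 analytically;
    # clear the floating-point residue
    low = 0.0 if successes == 0 else max(0.0, centre - half)
    high = 1.0 if successes == n else min(1.0, centre + half)
    return low, high


# ---------------------------------------------------------------------------
# Ranges and the one-way analysis
# ---------------------------------------------------------------------------

_PROB_FIELDS = ("p_marked", "recurrence_annual", "waning_annual",
                "p_reop_given_recurrence", "onset_delay_fraction")
_UTILITY_PREFIX = "u_"


def parameter_kind(path: str) -> str:
    """Classify a dotted parameter path as probability / utility / cost."""
    leaf = path.split(".")[1]
    if leaf in _PROB_FIELDS:
        return "probability"
    if leaf.startswith(_UTILITY_PREFIX):
        return "utility"
    return "cost"


@dataclass(frozen=True)
class ParamRange:
    """Low/high bounds for one parameter, tagged with their provenance."""

    path: str
    base: float
    low: float
    high: float
    source: str  # "ci95" or "pm20"

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise ValidationError(
                f"range for {self.path}: low <= base <= high violated "
                f"({self.low}, {self.base}, {self.high})"
            )


@dataclass(frozen=True)
class DsaRow:
    """One tornado row: ICERs with the parameter at its low and high bound."""

    path: str
    low_value: float
    high_value: float
    icer_low: float
    icer_high: float
    relative_change: float

    @property
    def span(self) -> float:
        return abs(self.icer_high - self.icer_low)


def build_ranges(
    inputs: ModelInputs,
    pm_fraction: float = 0.2,
    marked_counts: tuple[int, int] | None = (8, 9),
    confidence: float = 0.95,
    overrides: Mapping[str, tuple[float, float]] | None = None,
) -> list[ParamRange]:
    """One :class:`ParamRange` per variable parameter.

    ``marked_counts`` supplies the trial arm (successes, n) behind the
    marked-improvement proportion; its range is the Wilson ``confidence``
    interval.  ``overrides`` maps a parameter path to an explicit (low,
    high) pair, e.g. a published 95% CI.  Everything else gets
    ``+/- pm_fraction`` of base, clipped to the legal domain
    (probabilities and utilities to [0, 1], costs to [0, inf)).
    """
    overrides = dict(overrides or {})
    ranges = []
    for path in parameter_paths(inputs):
        base = get_param(inputs, path)
        kind = parameter_kind(path)
        if path in overrides:
            low, high = overrides[path]
            source = "ci95"
        elif path == "shared.p_marked" and marked_counts is not None:
            low, high = wilson_interval(*marked_counts, confidence)
            source = "ci95"
        else:
            low = base * (1.0 - pm_fraction)
            high = base * (1.0 + pm_fraction)
            source = "pm20"
        if kind in ("probability", "utility"):
            low, high = max(low, 0.0), min(high, 1.0)
        else:
            low = max(low, 0.0)
        low, high = min(low, base), max(high, base)
        ranges.append(ParamRange(path=path, base=base, low=low, high=high, source=source))
    return ranges


def _icer_value(inputs: ModelInputs, pair: tuple[StrategyName, StrategyName]) -> float:
    """Raw ΔC/ΔQ for a comparison (signed; may be negative under dominance)."""
    res = evaluate_all(inputs)
    c = compare(res[pair[0]], res[pair[1]])
    if c.delta_qaly == 0.0:
        return np.inf if c.delta_cost > 0 else (-np.inf if c.delta_cost < 0 else 0.0)
    return c.delta_cost / c.delta_qaly


def run_dsa(
    inputs: ModelInputs,
    ranges: Iterable[ParamRange] | None = None,
    comparisons: Mapping[str, tuple[StrategyName, StrategyName]] | None = None,
    report_threshold: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """One-way sensitivity analysis for each comparison.

    Re-evaluates the full model with each parameter at its low and at its
    high bound (all else at base) and keeps the rows where either bound
    moves the ICER by more than ``report_threshold`` relative to base,
    ordered by descending bound-to-bound ICER span (ties alphabetically).
    Set ``report_threshold=0`` to keep every row.
    """
    if ranges is None:
        ranges = build_ranges(inputs)
    if comparisons is None:
        comparisons = COMPARISONS
    base_icers = {key: _icer_value(inputs, pair) for key, pair in comparisons.items()}
    rows: dict[str, list[DsaRow]] = {key: [] for key in comparisons}
    for rng_ in ranges:
        low_inputs = set_param(inputs, rng_.path, rng_.low)
        high_inputs = set_param(inputs, rng_.path, rng_.high)
        for key, pair in comparisons.items():
            icer_low = _icer_value(low_inputs, pair)
            icer_high = _icer_value(high_inputs, pair)
            base = base_icers[key]
            denom = abs(base) if base not in (0.0, np.inf, -np.inf) else np.inf
            rel = max(abs(icer_low - base), abs(icer_high - base)) / denom
            if rel > report_threshold:
                rows[key].append(
                    DsaRow(rng_.path, rng_.low, rng_.high, icer_low, icer_high, rel)
                )
    out = {}
    for key in comparisons:
        ordered = sorted(rows[key], key=lambda r: (-r.span, r.path))
        out[key] = pd.DataFrame(
            [dataclasses.asdict(r) for r in ordered],
            columns=["path", "low_value", "high_value",
                     "icer_low", "icer_high", "relative_change"],
        )
    return out


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsaSpec:
    """How the Monte Carlo analysis parameterises its input distributions.

    ``sd_fraction`` is the default coefficient of variation (sd / mean) used
    for every parameter without a better-founded spread; the
    marked-improvement proportion instead derives its sd from the Wilson
    ``confidence`` interval of the ``marked_counts`` trial arm as
    ``(high - low) / (2 z)``.  ``overrides`` maps a parameter path to an
    explicit sd.  With ``sd_fraction = 0`` and ``marked_counts = None``
    every distribution degenerates to a point mass at the base value.
    """

    sd_fraction: float = 0.2
    marked_counts: tuple[int, int] | None = (8, 9)
    confidence: float = 0.95
    overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "overrides", dict(self.overrides))
        if self.sd_fraction < 0:
            raise ValidationError("sd_fraction must be >= 0")

    def sd_for(self, path: str, mean: float) -> float:
        if path in self.overrides:
            return float(self.overrides[path])
        if path == "shared.p_marked" and self.marked_counts is not None:
            low, high = wilson_interval(*self.marked_counts, self.confidence)
            z = float(stats.norm.ppf(0.5 + self.confidence / 2.0))
            return (high - low) / (2.0 * z)
        return self.sd_fraction * mean


def _draw_beta(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Method-of-moments beta draw; degenerate when sd = 0 or mean is 0/1."""
    if sd == 0.0 or mean in (0.0, 1.0):
        if not (0.0 <= mean <= 1.0):
            raise ValidationError(f"beta mean must lie in [0, 1], got {mean}")
        return mean
    if not (0.0 < mean < 1.0):
        raise ValidationError(f"beta mean must lie in (0, 1), got {mean}")
    var = sd * sd
    limit = mean * (1.0 - mean)
    if var >= limit:
        raise ValidationError(
            f"beta moment matching infeasible: sd {sd} too large for mean {mean}"
        )
    nu = limit / var - 1.0
    return float(rng.beta(mean * nu, (1.0 - mean) * nu))


def _draw_gamma(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Method-of-moments gamma draw: shape (mean/sd)^2, scale sd^2/mean."""
    if mean < 0:
        raise ValidationError(f"gamma mean must be >= 0, got {mean}")
    if sd == 0.0 or mean == 0.0:
        return mean
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return float(rng.gamma(shape, scale))


def _clip01(x: float) -> float:
    return min(1.0, max(0.0, x))


def sample_inputs(
    base: ModelInputs, spec: PsaSpec, rng: np.random.Generator
) -> ModelInputs:
    """Draw one Monte Carlo parameter set around ``base``.

    Shared draws (applied to every strategy): the marked-improvement
    proportion (the rest of the outcome simplex keeps the base
    mild-to-none ratio), the baseline utility (TR moves with it), the
    no-adverse-event marked-improvement utility, medication cost and the
    re-operation probability.  The no-AE mild/moderate utility is the
    midpoint of baseline and marked, mirroring how the base value was set.
    Strategy-specific AE-adjusted utilities move with the shared anchors,
    preserving their base-case offsets (clipped to [0, 1]).  Procedure
    cost, non-zero monitoring and adverse-event tariffs, recurrence and
    waning are drawn independently per strategy.
    """
    anchor_mt = max(
        (s.u_mt_y1 for s in base.strategies.values() if s.is_procedure),
        default=None,
    )
    # shared base values (validated identical across strategies by get_param)
    pm_base = get_param(base, "shared.p_marked") if any(
        s.is_procedure for s in base.strategies.values()
    ) else None
    u_bt_base = get_param(base, "shared.u_bt")
    med_base = get_param(base, "shared.medication_annual")
    reop_base = get_param(base, "shared.p_reop_given_recurrence")

    u_bt = _draw_beta(rng, u_bt_base, spec.sd_for("shared.u_bt", u_bt_base))
    med = _draw_gamma(rng, med_base, spec.sd_for("shared.medication_annual", med_base))
    reop = _draw_beta(
        rng, reop_base, spec.sd_for("shared.p_reop_given_recurrence", reop_base)
    )
    out = base
    if pm_base is not None:
        pm = _draw_beta(rng, pm_base, spec.sd_for("shared.p_marked", pm_base))
        if pm != pm_base:  # degenerate draws must leave the base bit-identical
            out = set_param(out, "shared.p_marked", pm)
    u_mt_anchor = None
    u_mmt_anchor = None
    if anchor_mt is not None:
        u_mt = _draw_beta(rng, anchor_mt, spec.sd_for("shared.u_mt", anchor_mt))
        u_mt_anchor, u_mmt_anchor = u_mt, (u_bt + u_mt) / 2.0
        anchor_mmt = (u_bt_base + anchor_mt) / 2.0

    strategies = {}
    for name, s in out.strategies.items():
        changes: dict = {"u_bt": u_bt, "u_tr": u_bt, "medication_annual": med}
        if s.is_procedure:
            changes["p_reop_given_recurrence"] = reop
            prefix = name.value
            pc_sd = spec.sd_for(f"{prefix}.procedure_cost", s.procedure_cost)
            changes["procedure_cost"] = _draw_gamma(rng, s.procedure_cost, pc_sd)
            for fname in ("recurrence_annual", "waning_annual"):
                mean = getattr(s, fname)
                changes[fname] = _draw_beta(
                    rng, mean, spec.sd_for(f"{prefix}.{fname}", mean)
                )
            for uname in ("u_mt_y1", "u_mt_y2plus"):
                offset = getattr(base.strategy(name), uname) - anchor_mt
                changes[uname] = _clip01(u_mt_anchor + offset)
            for uname in ("u_mmt_y1", "u_mmt_y2plus"):
                offset = getattr(base.strategy(name), uname) - anchor_mmt
                changes[uname] = _clip01(u_mmt_anchor + offset)
        monitoring = dict(s.monitoring_annual)
        for year, cost in monitoring.items():
            if cost > 0:
                sd = spec.sd_for(f"{name.value}.monitoring.{year}", cost)
                monitoring[year] = _draw_gamma(rng, cost, sd)
        changes["monitoring_annual"] = monitoring
        ae = dict(s.ae_costs)
        for ae_name, cost in ae.items():
            if cost > 0:
                sd = spec.sd_for(f"{name.value}.ae_costs.{ae_name}", cost)
                ae[ae_name] = _draw_gamma(rng, cost, sd)
        changes["ae_costs"] = ae
        strategies[name] = s.replace(**changes)
    return out.replace(strategies=strategies)


@dataclass(frozen=True)
class PSAResult:
    """Per-iteration incremental records for each comparison.

    ``frame`` has columns ``iteration, comparison, delta_cost, delta_qaly``;
    results are bit-identical for identical seeds.
    """

    frame: pd.DataFrame
    n_iterations: int
    seed: int

    def records(self, comparison: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.frame[self.frame["comparison"] == comparison]
        if len(sub) != self.n_iterations:
            raise ValidationError(f"unknown comparison {comparison!r}")
        return sub["delta_cost"].to_numpy(), sub["delta_qaly"].to_numpy()

    def fraction_dominant(self, comparison: str) -> float:
        dc, dq = self.records(comparison)
        return float(np.mean((dc < 0) & (dq > 0)))

    def fraction_cost_effective(self, comparison: str, wtp: float) -> float:
        dc, dq = self.records(comparison)
        return float(np.mean(wtp * dq - dc > 0))


def run_psa(
    base: ModelInputs,
    spec: PsaSpec | None = None,
    n_iterations: int = 1000,
    seed: int = 42,
    comparisons: Mapping[str, tuple[StrategyName, StrategyName]] | None = None,
) -> PSAResult:
    """Monte Carlo probabilistic sensitivity analysis.

    Each iteration draws one full parameter set (:func:`sample_inputs`) from
    its own counter-derived substream — iteration ``i`` always sees the same
    draws for a given ``seed``, regardless of ``n_iterations`` — evaluates
    every strategy, and records the incremental cost/QALY pair for each
    comparison.
    """
    if n_iterations < 1:
        raise ValidationError("n_iterations must be >= 1")
    if spec is None:
        spec = PsaSpec()
    if comparisons is None:
        comparisons = COMPARISONS
    rows = []
    for i in range(n_iterations):
        rng = np.random.default_rng(np.random.SeedSequence((seed, i)))
        sampled = sample_inputs(base, spec, rng)
        res = evaluate_all(sampled)
        for key, (a, b) in comparisons.items():
            rows.append(
                {
                    "iteration": i,
                    "comparison": key,
                    "delta_cost": res[a].total_cost - res[b].total_cost,
                    "delta_qaly": res[a].total_qaly - res[b].total_qaly,
                }
            )
    frame = pd.DataFrame(rows, columns=["iteration", "comparison", "delta_cost", "delta_qaly"])
    return PSAResult(frame=frame, n_iterations=n_iterations, seed=seed)


@dataclass(frozen=True)
class CeacCurve:
    """Probability of cost-effectiveness across willingness-to-pay values."""

    wtp: np.ndarray
    p_cost_effective: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "wtp", np.asarray(self.wtp, dtype=float))
        p = np.asarray(self.p_cost_effective, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValidationError("CEAC probabilities must lie in [0, 1]")
        object.__setattr__(self, "p_cost_effective", p)

    def at(self, wtp: float) -> float:
        idx = np.flatnonzero(np.isclose(self.wtp, wtp))
        if idx.size == 0:
            raise ValidationError(f"wtp {wtp} not on the curve's grid")
        return float(self.p_cost_effective[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "p_cost_effective": self.p_cost_effective})


def ceac(psa: PSAResult, wtp_grid: Iterable[float]) -> dict[str, CeacCurve]:
    """Cost-effectiveness acceptability curve per comparison.

    At each willingness-to-pay value the curve is the fraction of PSA
    iterations with positive incremental net monetary benefit
    ``wtp * ΔQ - ΔC``.
    """
    wtp = np.asarray(list(wtp_grid), dtype=float)
    curves = {}
    for key in psa.frame["comparison"].unique():
        dc, dq = psa.records(key)
        nmb = wtp[:, None] * dq[None, :] - dc[None, :]
        curves[key] = CeacCurve(wtp=wtp, p_cost_effective=(nmb > 0).mean(axis=1))
    return curves
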