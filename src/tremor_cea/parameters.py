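"""Domain types and configuration handling for the tremor treatment model.

All model inputs live here: per-strategy clinical effectiveness, costs and
utilities (:class:`StrategyInputs`), economic settings such as the discount
rate and time horizon (:class:`EconSettings`), and the all-cause mortality
schedule (:class:`LifeTable`).  The bundled base case — a 2019-GBP NHS
England parameterisation of unilateral MRgFUS, unilateral DBS and
medication-only care for medically refractory essential tremor — ships as a
YAML document plus a small life-table CSV under ``tremor_cea/data`` and is
loaded with :func:`base_case`.

Every loader validates its invariants (outcome proportions summing to one,
probabilities and utilities in [0, 1], non-negative costs, contiguous life
table ages) and raises :class:`SchemaError` or :class:`ValidationError`
naming the offending field.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "HealthState",
    "StrategyName",
    "StrategyInputs",
    "EconSettings",
    "LifeTable",
    "ModelInputs",
    "SchemaError",
    "ValidationError",
    "blended_mortality",
    "load_config",
    "save_config",
    "base_case",
    "bundled_life_table",
    "get_param",
    "set_param",
    "parameter_paths",
]

_PROB_TOL = 1e-9


class SchemaError(KeyError):
    """A required configuration key is missing or malformed."""


class ValidationError(ValueError):
    """A model input violates one of its documented invariants."""


class HealthState(enum.IntEnum):
    """The five Markov states.

    ``BT`` baseline (disabling) tremor, ``MMT`` mild-to-moderately improved,
    ``MT`` markedly improved, ``TR`` tremor recurrence awaiting re-operation
    (transient, occupied for at most one cycle), ``DEAD`` absorbing death.
    The integer values index the transition matrix and trace columns.
    """

    BT = 0
    MMT = 1
    MT = 2
    TR = 3
    DEAD = 4


N_STATES = len(HealthState)


class StrategyName(str, enum.Enum):
    MRGFUS = "mrgfus"
    DBS = "dbs"
    NONE = "none"


@dataclass(frozen=True)
class StrategyInputs:
    """All clinical, cost and utility parameters for one treatment strategy.

    Costs are 2019 GBP.  ``procedure_cost`` is a bundled tariff covering
    ``bundle_years`` years of routine monitoring, so ``monitoring_annual``
    (a map *from-year* -> GBP/year, later bands overriding earlier ones)
    is zero inside the bundle.  Utilities are adverse-event-adjusted and
    split into a first-year and a steady-state (year 2+) value.
    ``onset_delay_fraction`` is the fraction of the first cycle spent at
    baseline utility before treatment benefit begins (0 for MRgFUS, 0.25
    for DBS whose stimulator needs ~3 months of optimisation).
    """

    name: StrategyName
    p_marked: float
    p_mild: float
    p_none: float
    waning_annual: float
    recurrence_annual: float
    p_reop_given_recurrence: float
    onset_delay_fraction: float
    procedure_cost: float
    bundle_years: int
    monitoring_annual: Mapping[int, float]
    medication_annual: float
    u_bt: float
    u_tr: float
    u_mt_y1: float
    u_mt_y2plus: float
    u_mmt_y1: float
    u_mmt_y2plus: float
    ae_costs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "monitoring_annual", dict(self.monitoring_annual))
        object.__setattr__(self, "ae_costs", dict(self.ae_costs))
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        for f in ("p_marked", "p_mild", "p_none", "waning_annual",
                  "recurrence_annual", "p_reop_given_recurrence",
                  "onset_delay_fraction"):
            _check_unit_interval(f, getattr(self, f), "probability")
        for f in ("u_bt", "u_tr", "u_mt_y1", "u_mt_y2plus",
                  "u_mmt_y1", "u_mmt_y2plus"):
            _check_unit_interval(f, getattr(self, f), "utility")
        if self.procedure_cost < 0:
            raise ValidationError("procedure_cost: cost must be >= 0")
        if self.medication_annual < 0:
            raise ValidationError("medication_annual: cost must be >= 0")
        for year, cost in self.monitoring_annual.items():
            if int(year) < 1:
                raise ValidationError("monitoring_annual: from-year bands must be >= 1")
            if cost < 0:
                raise ValidationError(f"monitoring_annual[{year}]: cost must be >= 0")
        for name, cost in self.ae_costs.items():
            if cost < 0:
                raise ValidationError(f"ae_costs[{name}]: cost must be >= 0")
        total = self.p_marked + self.p_mild + self.p_none
        if abs(total - 1.0) > _PROB_TOL:
            raise ValidationError(
                f"p_marked + p_mild + p_none must equal 1 (got {total!r})"
            )
        if self.bundle_years < 0:
            raise ValidationError("bundle_years: must be a non-negative integer")
        if not self.monitoring_annual or min(int(y) for y in self.monitoring_annual) != 1:
            raise ValidationError("monitoring_annual: a band starting at year 1 is required")
        if self.name is StrategyName.NONE:
            if self.p_marked != 0.0 or self.p_mild != 0.0 or self.p_none != 1.0:
                raise ValidationError(
                    "none strategy: p_marked = p_mild = 0 and p_none = 1 required"
                )
            if self.procedure_cost != 0.0:
                raise ValidationError("none strategy: procedure_cost must be 0")

    @property
    def is_procedure(self) -> bool:
        return self.name is not StrategyName.NONE

    def monitoring_for_year(self, year: int) -> float:
        """Annual monitoring cost applying in model year ``year`` (1-based)."""
        if year < 1:
            raise ValidationError(f"monitoring year must be >= 1, got {year}")
        applicable = [int(y) for y in self.monitoring_annual if int(y) <= year]
        if not applicable:
            raise SchemaError(
                f"{self.name.value}: no monitoring band covers year {year}"
            )
        return float(self.monitoring_annual[max(applicable)])

    def replace(self, **changes) -> "StrategyInputs":
        return dataclasses.replace(self, **changes)


def _check_unit_interval(name: str, value: float, kind: str) -> None:
    if not (0.0 <= value <= 1.0) or not np.isfinite(value):
        raise ValidationError(f"{name}: {kind} must lie in [0, 1], got {value!r}")


DEFAULT_WTP_GRID = tuple(float(w) for w in range(0, 100_001, 1000))


@dataclass(frozen=True)
class EconSettings:
    """Economic evaluation settings (NICE reference-case defaults)."""

    discount_rate: float = 0.035
    horizon_years: int = 5
    cycle_years: int = 1
    start_age: int = 70
    male_fraction: float = 0.46
    wtp_grid: tuple = DEFAULT_WTP_GRID
    population_size: int = 1415

    def __post_init__(self) -> None:
        object.__setattr__(self, "wtp_grid", tuple(float(w) for w in self.wtp_grid))
        if self.discount_rate < 0:
            raise ValidationError("discount_rate: must be >= 0")
        if self.horizon_years < 1:
            raise ValidationError("horizon_years: must be >= 1")
        if self.cycle_years != 1:
            raise ValidationError("cycle_years: only 1-year cycles are supported")
        if not (0.0 <= self.male_fraction <= 1.0):
            raise ValidationError("male_fraction: must lie in [0, 1]")
        grid = np.asarray(self.wtp_grid)
        if grid.size and np.any(np.diff(grid) <= 0):
            raise ValidationError("wtp_grid: values must be strictly increasing")
        if self.population_size < 1:
            raise ValidationError("population_size: must be >= 1")

    def replace(self, **changes) -> "EconSettings":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual all-cause death probabilities, by sex.

    Cohort mortality is the male/female blend
    ``male_fraction * q_male + (1 - male_fraction) * q_female``
    (see :func:`blended_mortality`); ages must be contiguous integers.
    """

    ages: np.ndarray
    q_male: np.ndarray
    q_female: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qm = np.asarray(self.q_male, dtype=float)
        qf = np.asarray(self.q_female, dtype=float)
        if not (len(ages) == len(qm) == len(qf)) or len(ages) == 0:
            raise ValidationError("life table: columns must be equal-length and non-empty")
        if np.any(np.diff(ages) != 1):
            raise ValidationError("life table: ages must be contiguous integers")
        for name, q in (("q_male", qm), ("q_female", qf)):
            if np.any((q < 0) | (q > 1) | ~np.isfinite(q)):
                raise ValidationError(f"life table: {name} must lie in [0, 1]")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q_male", qm)
        object.__setattr__(self, "q_female", qf)

    @property
    def age_min(self) -> int:
        return int(self.ages[0])

    @property
    def age_max(self) -> int:
        return int(self.ages[-1])

    def covers(self, start_age: int, horizon_years: int) -> bool:
        return self.age_min <= start_age and start_age + horizon_years - 1 <= self.age_max

    def q_at(self, age: int, column: str) -> float:
        if not (self.age_min <= age <= self.age_max):
            raise ValidationError(
                f"age {age} outside life table range [{self.age_min}, {self.age_max}]"
            )
        idx = age - self.age_min
        return float(getattr(self, column)[idx])

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        missing = {"age", "q_male", "q_female"} - set(df.columns)
        if missing:
            raise SchemaError(f"life table CSV missing columns: {sorted(missing)}")
        df = df.sort_values("age")
        return cls(df["age"].to_numpy(), df["q_male"].to_numpy(), df["q_female"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"age": self.ages, "q_male": self.q_male, "q_female": self.q_female}
        ).to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "q_male": self.q_male, "q_female": self.q_female}
        )


def blended_mortality(lt: LifeTable, age: int, male_fraction: float) -> float:
    """Sex-blended annual death probability at ``age``.

    ``male_fraction * q_male(age) + (1 - male_fraction) * q_female(age)``.
    Raises :class:`ValidationError` if ``age`` falls outside the table.
    """
    if not (0.0 <= male_fraction <= 1.0):
        raise ValidationError("male_fraction: must lie in [0, 1]")
    qm = lt.q_at(age, "q_male")
    qf = lt.q_at(age, "q_female")
    return male_fraction * qm + (1.0 - male_fraction) * qf


@dataclass(frozen=True)
class ModelInputs:
    """A complete, validated model parameterisation."""

    strategies: Mapping[StrategyName, StrategyInputs]
    settings: EconSettings
    life_table: LifeTable

    def __post_init__(self) -> None:
        object.__setattr__(self, "strategies", dict(self.strategies))
        for name, s in self.strategies.items():
            if s.name is not name:
                raise ValidationError(f"strategy key {name} does not match inputs.name")

    def strategy(self, name: StrategyName | str) -> StrategyInputs:
        name = StrategyName(name)
        try:
            return self.strategies[name]
        except KeyError as exc:
            raise SchemaError(f"strategy {name.value!r} not configured") from exc

    @property
    def mrgfus(self) -> StrategyInputs:
        return self.strategy(StrategyName.MRGFUS)

    @property
    def dbs(self) -> StrategyInputs:
        return self.strategy(StrategyName.DBS)

    @property
    def none(self) -> StrategyInputs:
        return self.strategy(StrategyName.NONE)

    def replace(self, **changes) -> "ModelInputs":
        return dataclasses.replace(self, **changes)

    def with_strategy(self, s: StrategyInputs) -> "ModelInputs":
        strategies = dict(self.strategies)
        strategies[s.name] = s
        return self.replace(strategies=strategies)

    def with_settings(self, **changes) -> "ModelInputs":
        return self.replace(settings=self.settings.replace(**changes))


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

_STRATEGY_REQUIRED = [
    "p_marked", "p_mild", "p_none", "waning_annual", "recurrence_annual",
    "p_reop_given_recurrence", "onset_delay_fraction", "procedure_cost",
    "bundle_years", "monitoring_annual", "medication_annual",
    "u_bt", "u_tr", "u_mt_y1", "u_mt_y2plus", "u_mmt_y1", "u_mmt_y2plus",
]


def _parse_strategy(name: StrategyName, raw: Mapping) -> StrategyInputs:
    if not isinstance(raw, Mapping):
        raise SchemaError(f"strategies.{name.value}: expected a mapping")
    missing = [k for k in _STRATEGY_REQUIRED if k not in raw]
    if missing:
        raise SchemaError(f"strategies.{name.value}: missing required keys {missing}")
    unfilled = [k for k in _STRATEGY_REQUIRED if raw[k] is None]
    if unfilled:
        raise SchemaError(
            f"strategies.{name.value}: keys {unfilled} have no value "
            "(unfilled template?)"
        )
    monitoring = {int(k): float(v) for k, v in dict(raw["monitoring_annual"]).items()}
    ae = {str(k): float(v) for k, v in dict(raw.get("ae_costs", {})).items()}
    kwargs = {k: raw[k] for k in _STRATEGY_REQUIRED
              if k not in ("monitoring_annual", "bundle_years")}
    return StrategyInputs(
        name=name,
        bundle_years=int(raw["bundle_years"]),
        monitoring_annual=monitoring,
        ae_costs=ae,
        **{k: float(v) for k, v in kwargs.items()},
    )


def _parse_settings(raw: Mapping) -> EconSettings:
    raw = dict(raw or {})
    wtp = raw.pop("wtp_grid", None)
    if wtp is None:
        grid = DEFAULT_WTP_GRID
    elif isinstance(wtp, Mapping):
        for key in ("start", "stop", "step"):
            if key not in wtp:
                raise SchemaError(f"settings.wtp_grid: missing key {key!r}")
        grid = tuple(
            float(w) for w in np.arange(wtp["start"], wtp["stop"] + wtp["step"] / 2, wtp["step"])
        )
    else:
        grid = tuple(float(w) for w in wtp)
    known = {f.name for f in dataclasses.fields(EconSettings)}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"settings: unknown keys {sorted(unknown)}")
    return EconSettings(wtp_grid=grid, **raw)


def load_config(path) -> ModelInputs:
    """Load and validate a model configuration (YAML or JSON document).

    The document has sections ``strategies`` (sub-keys ``mrgfus``, ``dbs``,
    ``none``), ``settings`` and ``life_table`` (path to a CSV with columns
    ``age,q_male,q_female``, resolved relative to the config file; omit it to
    use the bundled schedule).  Optional ``psa``/``dsa`` sections are parsed
    by :mod:`tremor_cea.sensitivity`.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise SchemaError("config root: expected a mapping")
    if "strategies" not in raw:
        raise SchemaError("config: missing required section 'strategies'")
    strategies = {}
    for name in StrategyName:
        if name.value in raw["strategies"]:
            strategies[name] = _parse_strategy(name, raw["strategies"][name.value])
    if not strategies:
        raise SchemaError("config: 'strategies' defines no known strategy")
    settings = _parse_settings(raw.get("settings", {}))
    lt_path = raw.get("life_table")
    if lt_path is None:
        life_table = bundled_life_table()
    else:
        life_table = LifeTable.from_csv((path.parent / lt_path).resolve())
    mi = ModelInputs(strategies=strategies, settings=settings, life_table=life_table)
    if not life_table.covers(settings.start_age, settings.horizon_years):
        raise ValidationError(
            "life table does not cover "
            f"[{settings.start_age}, {settings.start_age + settings.horizon_years - 1}]"
        )
    return mi


def save_config(inputs: ModelInputs, path, life_table_path=None) -> None:
    """Write ``inputs`` as a YAML config (round-trips through :func:`load_config`)."""
    path = Path(path)
    doc = {
        "settings": {
            "discount_rate": inputs.settings.discount_rate,
            "horizon_years": inputs.settings.horizon_years,
            "cycle_years": inputs.settings.cycle_years,
            "start_age": inputs.settings.start_age,
            "male_fraction": inputs.settings.male_fraction,
            "wtp_grid": list(inputs.settings.wtp_grid),
            "population_size": inputs.settings.population_size,
        },
        "strategies": {
            name.value: _strategy_doc(s) for name, s in inputs.strategies.items()
        },
    }
    if life_table_path is not None:
        lt_path = Path(life_table_path)
        inputs.life_table.to_csv(path.parent / lt_path)
        doc["life_table"] = str(lt_path)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _strategy_doc(s: StrategyInputs) -> dict:
    doc = {k: getattr(s, k) for k in _STRATEGY_REQUIRED
           if k not in ("monitoring_annual", "bundle_years")}
    doc["bundle_years"] = s.bundle_years
    doc["monitoring_annual"] = {int(k): float(v) for k, v in s.monitoring_annual.items()}
    doc["ae_costs"] = dict(s.ae_costs)
    return doc


def _data_path(name: str):
    return resources.files("tremor_cea").joinpath("data").joinpath(name)


def bundled_life_table() -> LifeTable:
    """The packaged synthetic England-style life table (ages 40-85)."""
    with resources.as_file(_data_path("life_table_england_synthetic.csv")) as p:
        return LifeTable.from_csv(p)


def base_case() -> ModelInputs:
    """The bundled base-case parameterisation (England, 2019 GBP)."""
    with resources.as_file(_data_path("base_case.yaml")) as p:
        return load_config(p)


# ---------------------------------------------------------------------------
# Parameter paths (used by the one-way and probabilistic sensitivity analyses)
# ---------------------------------------------------------------------------

_SHARED_FIELDS = ("p_marked", "medication_annual", "p_reop_given_recurrence", "u_bt")
_SHARED_PROCEDURE_ONLY = frozenset({"p_marked", "p_reop_given_recurrence"})
_STRATEGY_FIELDS = (
    "procedure_cost", "recurrence_annual", "waning_annual",
    "u_mt_y1", "u_mt_y2plus", "u_mmt_y1", "u_mmt_y2plus",
)


def parameter_paths(inputs: ModelInputs) -> list[str]:
    """Dotted paths of every individually variable numeric parameter.

    ``shared.*`` paths move the value in every configured strategy at once
    (the outcome-proportion path re-normalises ``p_mild``/``p_none`` to keep
    the simplex); ``<strategy>.<field>`` paths are strategy-specific, with
    ``monitoring.<from_year>`` and ``ae_costs.<name>`` for the mapped costs.
    """
    paths = [f"shared.{f}" for f in _SHARED_FIELDS]
    for name, s in inputs.strategies.items():
        if s.is_procedure:
            paths.extend(f"{name.value}.{f}" for f in _STRATEGY_FIELDS)
        for year, cost in sorted(s.monitoring_annual.items()):
            if cost > 0:
                paths.append(f"{name.value}.monitoring.{year}")
        for ae in sorted(s.ae_costs):
            paths.append(f"{name.value}.ae_costs.{ae}")
    return paths


def get_param(inputs: ModelInputs, path: str) -> float:
    head, _, rest = path.partition(".")
    if head == "shared":
        strategies = list(inputs.strategies.values())
        values = {getattr(s, rest) for s in strategies
                  if rest not in _SHARED_PROCEDURE_ONLY or s.is_procedure}
        if len(values) != 1:
            raise ValidationError(f"shared path {path!r}: strategies disagree ({values})")
        return values.pop()
    s = inputs.strategy(head)
    field_name, _, sub = rest.partition(".")
    if field_name == "monitoring":
        return s.monitoring_for_year(int(sub))
    if field_name == "ae_costs":
        return float(s.ae_costs[sub])
    if not hasattr(s, field_name):
        raise SchemaError(f"unknown parameter path {path!r}")
    return float(getattr(s, field_name))


def set_param(inputs: ModelInputs, path: str, value: float) -> ModelInputs:
    """Return a copy of ``inputs`` with the parameter at ``path`` set.

    Setting ``shared.p_marked`` rescales each procedure strategy's
    ``p_mild``/``p_none`` proportionally so the outcome simplex still sums
    to one; setting ``shared.u_bt`` also moves ``u_tr`` (equal by model
    assumption).
    """
    head, _, rest = path.partition(".")
    out = inputs
    if head == "shared":
        for s in inputs.strategies.values():
            if rest in _SHARED_PROCEDURE_ONLY and not s.is_procedure:
                continue
            if rest == "p_marked":
                out = out.with_strategy(_rescaled_outcomes(s, value))
            elif rest == "u_bt":
                out = out.with_strategy(s.replace(u_bt=value, u_tr=value))
            else:
                out = out.with_strategy(s.replace(**{rest: value}))
        return out
    s = inputs.strategy(head)
    field_name, _, sub = rest.partition(".")
    if field_name == "monitoring":
        monitoring = dict(s.monitoring_annual)
        if int(sub) not in monitoring:
            raise SchemaError(f"unknown parameter path {path!r}")
        monitoring[int(sub)] = float(value)
        return out.with_strategy(s.replace(monitoring_annual=monitoring))
    if field_name == "ae_costs":
        ae = dict(s.ae_costs)
        if sub not in ae:
            raise SchemaError(f"unknown parameter path {path!r}")
        ae[sub] = float(value)
        return out.with_strategy(s.replace(ae_costs=ae))
    if not hasattr(s, field_name):
        raise SchemaError(f"unknown parameter path {path!r}")
    return out.with_strategy(s.replace(**{field_name: float(value)}))


def _rescaled_outcomes(s: StrategyInputs, p_marked: float) -> StrategyInputs:
    remainder = s.p_mild + s.p_none
    if remainder <= 0:
        return s.replace(p_marked=p_marked, p_mild=1.0 - p_marked, p_none=0.0)
    scale = (1.0 - p_marked) / remainder
    return s.replace(
        p_marked=p_marked, p_mild=s.p_mild * scale, p_none=s.p_none * scale
    )
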