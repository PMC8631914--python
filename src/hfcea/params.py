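"""Typed model parameters and configuration loading.

The default parameter set transcribes the published model inputs for the Chinese
HFrEF cost-utility analysis of add-on dapagliflozin/empagliflozin: quarterly
event probabilities per trial arm, the NYHA class transition matrix, age-banded
non-cardiovascular mortality, per-cycle utilities, costs in 2020 USD, and the
run settings (start age 66, 40 quarterly cycles, 5% annual discount,
willingness-to-pay = 1x 2019 Chinese GDP per capita).

Users can override any subset of inputs through a YAML/JSON config file; omitted
fields fall back to the bundled defaults and the merged set is re-validated.
"""

from __future__ import annotations

import copy
import enum
import importlib.resources
import json
import math
from dataclasses import dataclass, field, replace
from typing import Any, Iterator, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "HealthState",
    "NYHA_STATES",
    "StrategyParams",
    "NYHATransitionMatrix",
    "AgeMortalityTable",
    "UtilityInputs",
    "ModelSettings",
    "ParameterSpec",
    "ParameterSet",
    "ConfigError",
    "STRATEGY_PAIRS",
    "paper_default_params",
    "load_config",
]

_ROW_SUM_TOL = 1e-9


class ConfigError(ValueError):
    """Raised when a parameter set or config file violates an invariant."""


class HealthState(enum.Enum):
    """The six model states: four NYHA classes plus two absorbing death states.

    Death is split by cause (cardiovascular vs non-cardiovascular) so the model
    can report cause-specific cumulative mortality; "dead" occupancy is the sum.
    """

    NYHA1 = 0
    NYHA2 = 1
    NYHA3 = 2
    NYHA4 = 3
    DEAD_CV = 4
    DEAD_NONCV = 5

    @property
    def is_death(self) -> bool:
        return self in (HealthState.DEAD_CV, HealthState.DEAD_NONCV)


NYHA_STATES = (
    HealthState.NYHA1,
    HealthState.NYHA2,
    HealthState.NYHA3,
    HealthState.NYHA4,
)

#: Trial-matched comparisons: each SGLT2 arm is compared only against the
#: placebo arm of its own source trial.
STRATEGY_PAIRS: dict[str, tuple[str, str]] = {
    "dapa": ("dapagliflozin", "control1"),
    "empa": ("empagliflozin", "control2"),
}


def _check_prob(value: float, path: str) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ConfigError(f"{path}: probability {value!r} outside [0, 1]")
    return value


def _check_nonneg(value: float, path: str) -> float:
    value = float(value)
    if value < 0.0:
        raise ConfigError(f"{path}: cost {value!r} is negative")
    return value


@dataclass(frozen=True)
class StrategyParams:
    """All per-cycle inputs defining one treatment arm."""

    name: str
    cv_death_per_cycle: float
    hosp_per_cycle: float
    readmit_per_hosp: float
    drug_cost_per_cycle: float
    standard_cost_per_cycle: float
    hosp_cost_per_event: float

    def validate(self) -> "StrategyParams":
        for f in ("cv_death_per_cycle", "hosp_per_cycle", "readmit_per_hosp"):
            _check_prob(getattr(self, f), f"strategy {self.name}.{f}")
        for f in ("drug_cost_per_cycle", "standard_cost_per_cycle", "hosp_cost_per_event"):
            _check_nonneg(getattr(self, f), f"strategy {self.name}.{f}")
        return self


class NYHATransitionMatrix:
    """4x4 quarterly transition matrix among NYHA classes (survivors only).

    Row i gives the distribution of next-cycle NYHA class for a patient in
    class i+1 who survives the cycle; every row must sum to one.
    """

    def __init__(self, rows: Sequence[Sequence[float]]):
        arr = np.asarray(rows, dtype=float)
        if arr.shape != (4, 4):
            raise ConfigError(f"nyha_matrix: expected 4x4, got {arr.shape}")
        if np.any(arr < 0) or np.any(arr > 1):
            raise ConfigError("nyha_matrix: entries outside [0, 1]")
        sums = arr.sum(axis=1)
        for i, s in enumerate(sums):
            if abs(s - 1.0) > _ROW_SUM_TOL:
                raise ConfigError(
                    f"nyha_matrix row {i + 1} (from NYHA {'I' * (i + 1)}) sums to {s!r}, not 1"
                )
        self._rows = arr
        self._rows.setflags(write=False)

    @property
    def rows(self) -> np.ndarray:
        return self._rows

    def row(self, nyha_class: int) -> np.ndarray:
        """1-based NYHA class row."""
        return self._rows[nyha_class - 1]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, NYHATransitionMatrix) and np.array_equal(
            self._rows, other._rows
        )

    def to_lists(self) -> list[list[float]]:
        return self._rows.tolist()


@dataclass(frozen=True)
class AgeMortalityTable:
    """Age-banded per-cycle non-cardiovascular death probabilities.

    Bands are half-open ``[age_low, age_high)`` and must be contiguous; the
    last band is carried forward for ages beyond it (documented extrapolation
    used for horizons reaching past the oldest tabulated band).
    """

    bands: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ConfigError("noncv_mortality: no age bands")
        prev_high = None
        for low, high, p in self.bands:
            if high <= low:
                raise ConfigError(f"noncv_mortality: band [{low}, {high}) is empty")
            if prev_high is not None and not math.isclose(low, prev_high):
                raise ConfigError(
                    f"noncv_mortality: bands not contiguous at age {prev_high}->{low}"
                )
            _check_prob(p, f"noncv_mortality band [{low}, {high})")
            prev_high = high

    def lookup(self, age: float) -> float:
        if age < self.bands[0][0]:
            raise ConfigError(
                f"noncv_mortality: age {age} below first band ({self.bands[0][0]})"
            )
        for low, high, p in self.bands:
            if low <= age < high:
                return p
        return self.bands[-1][2]  # carry the last band forward

    def to_dicts(self) -> list[dict[str, float]]:
        return [
            {"age_low": lo, "age_high": hi, "prob": p} for lo, hi, p in self.bands
        ]


@dataclass(frozen=True)
class UtilityInputs:
    """Per-cycle QALY weights by NYHA class plus a one-off event decrement.

    Utilities here are per 3-month cycle (a full cycle in NYHA II accrues
    0.18 QALYs); each hospitalization or readmission event additionally
    subtracts 0.1 QALYs once.
    """

    per_cycle_utility: Mapping[str, float]
    event_disutility: float

    def validate(self, *, strict_monotone: bool = False) -> "UtilityInputs":
        # Monotonicity (utility non-increasing NYHA I -> IV) is enforced only
        # for user-authored configs: sensitivity analyses legitimately perturb
        # a single class utility beyond its neighbour's base-case value.
        vals = []
        for st in NYHA_STATES:
            if st.name not in self.per_cycle_utility:
                raise ConfigError(f"utilities: missing {st.name}")
            vals.append(_check_prob(self.per_cycle_utility[st.name], f"utilities.{st.name}"))
        if strict_monotone and any(vals[i] < vals[i + 1] - 1e-12 for i in range(3)):
            raise ConfigError("utilities: must be non-increasing from NYHA I to IV")
        if self.event_disutility > 0:
            raise ConfigError("utilities.event_disutility must be <= 0")
        return self

    def utility_of(self, state: HealthState) -> float:
        return 0.0 if state.is_death else float(self.per_cycle_utility[state.name])

    def as_vector(self) -> np.ndarray:
        """Length-6 utility vector over the model's state ordering."""
        return np.array(
            [self.per_cycle_utility[s.name] for s in NYHA_STATES] + [0.0, 0.0]
        )


@dataclass(frozen=True)
class ModelSettings:
    """Run settings: cohort, horizon, discounting and accounting conventions."""

    start_age: float = 66.0
    cycle_length_years: float = 0.25
    horizon_years: float = 10.0
    annual_discount: float = 0.05
    wtp_per_qaly: float = 11008.07
    gdp_per_capita: float = 11008.07
    initial_distribution: tuple[float, float, float, float] = (0.0, 0.713, 0.28, 0.007)
    half_cycle_correction: bool = True
    discount_convention: str = "mid_cycle"
    discount_event_disutility: bool = False
    noncv_mortality_is_annual: bool = False
    sample_nyha_matrix: bool = True
    dirichlet_concentration: float = 1000.0

    def validate(self) -> "ModelSettings":
        if self.cycle_length_years <= 0:
            raise ConfigError("settings.cycle_length_years must be positive")
        n = self.horizon_years / self.cycle_length_years
        if self.horizon_years < 0 or abs(n - round(n)) > 1e-9:
            raise ConfigError(
                f"settings.horizon_years ({self.horizon_years}) must be a positive "
                f"integer multiple of cycle_length_years ({self.cycle_length_years})"
            )
        if self.annual_discount < 0:
            raise ConfigError("settings.annual_discount must be >= 0")
        dist = np.asarray(self.initial_distribution, dtype=float)
        if dist.shape != (4,):
            raise ConfigError("settings.initial_distribution must have 4 entries")
        if np.any(dist < 0) or abs(dist.sum() - 1.0) > _ROW_SUM_TOL:
            raise ConfigError(
                f"settings.initial_distribution must be non-negative and sum to 1 "
                f"(got sum {dist.sum()!r})"
            )
        if self.discount_convention not in ("mid_cycle", "start_of_cycle"):
            raise ConfigError(
                f"settings.discount_convention {self.discount_convention!r} not one of "
                "mid_cycle/start_of_cycle"
            )
        return self

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon_years / self.cycle_length_years))


@dataclass(frozen=True)
class ParameterSpec:
    """Uncertainty declaration for one scalar input (OWSA range + PSA family)."""

    path: str
    mean: float
    low: float
    high: float
    distribution: str  # beta | gamma | dirichlet_row | fixed

    def __post_init__(self) -> None:
        if self.distribution not in ("beta", "gamma", "dirichlet_row", "fixed"):
            raise ConfigError(f"{self.path}: unknown distribution {self.distribution!r}")
        if self.low > self.high + 1e-12:
            raise ConfigError(f"{self.path}: low {self.low} > high {self.high}")

    @property
    def is_degenerate(self) -> bool:
        return math.isclose(self.low, self.high)


@dataclass
class _ArmRates:
    cv_death_per_cycle: float
    hosp_per_cycle: float
    drug_cost_per_cycle: float


@dataclass
class _SharedCosts:
    standard_per_cycle: float
    hosp_per_event: float


@dataclass
class ParameterSet:
    """The full model input set: four arms plus shared structure.

    Shared inputs (standard-treatment cost, hospitalization cost, readmission
    probability, NYHA matrix, background mortality, utilities) are stored once
    and apply to every arm; :meth:`strategy` assembles the flat per-arm view.
    """

    arms: dict[str, _ArmRates]
    readmit_per_hosp: float
    costs: _SharedCosts
    nyha_matrix: NYHATransitionMatrix
    noncv_mortality: AgeMortalityTable
    utilities: UtilityInputs
    settings: ModelSettings
    parameter_specs: list[ParameterSpec] = field(default_factory=list)

    # -- assembly ---------------------------------------------------------

    def strategy(self, name: str) -> StrategyParams:
        if name not in self.arms:
            raise KeyError(
                f"unknown strategy {name!r}; available: {sorted(self.arms)}"
            )
        arm = self.arms[name]
        return StrategyParams(
            name=name,
            cv_death_per_cycle=arm.cv_death_per_cycle,
            hosp_per_cycle=arm.hosp_per_cycle,
            readmit_per_hosp=self.readmit_per_hosp,
            drug_cost_per_cycle=arm.drug_cost_per_cycle,
            standard_cost_per_cycle=self.costs.standard_per_cycle,
            hosp_cost_per_event=self.costs.hosp_per_event,
        ).validate()

    def pair(self, key: str) -> tuple[str, str]:
        if key in STRATEGY_PAIRS:
            return STRATEGY_PAIRS[key]
        raise KeyError(f"unknown pair {key!r}; available: {sorted(STRATEGY_PAIRS)}")

    def validate(self) -> "ParameterSet":
        for name in self.arms:
            self.strategy(name)
        self.utilities.validate()
        self.settings.validate()
        seen = set()
        for spec in self.parameter_specs:
            if spec.path in seen:
                raise ConfigError(f"parameter_specs: duplicate path {spec.path}")
            seen.add(spec.path)
            self.get_param(spec.path)  # must resolve
        return self

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    # -- dotted-path access (used by OWSA, scenarios and the PSA) ---------

    def get_param(self, path: str) -> Any:
        return _traverse(self, path, set_value=None)

    def set_param(self, path: str, value: Any) -> None:
        _traverse(self, path, set_value=(value,))

    def with_overrides(self, overrides: Mapping[str, Any]) -> "ParameterSet":
        new = self.copy()
        for path, value in overrides.items():
            new.set_param(path, value)
        return new.validate()

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "arms": {
                name: {
                    "cv_death_per_cycle": a.cv_death_per_cycle,
                    "hosp_per_cycle": a.hosp_per_cycle,
                    "drug_cost_per_cycle": a.drug_cost_per_cycle,
                }
                for name, a in self.arms.items()
            },
            "readmit_per_hosp": self.readmit_per_hosp,
            "costs": {
                "standard_per_cycle": self.costs.standard_per_cycle,
                "hosp_per_event": self.costs.hosp_per_event,
            },
            "nyha_matrix": self.nyha_matrix.to_lists(),
            "noncv_mortality": self.noncv_mortality.to_dicts(),
            "utilities": {
                **{k: float(v) for k, v in self.utilities.per_cycle_utility.items()},
                "event_disutility": self.utilities.event_disutility,
            },
            "settings": {
                "start_age": self.settings.start_age,
                "cycle_length_years": self.settings.cycle_length_years,
                "horizon_years": self.settings.horizon_years,
                "annual_discount": self.settings.annual_discount,
                "wtp_per_qaly": self.settings.wtp_per_qaly,
                "gdp_per_capita": self.settings.gdp_per_capita,
                "initial_distribution": list(self.settings.initial_distribution),
                "half_cycle_correction": self.settings.half_cycle_correction,
                "discount_convention": self.settings.discount_convention,
                "discount_event_disutility": self.settings.discount_event_disutility,
                "noncv_mortality_is_annual": self.settings.noncv_mortality_is_annual,
                "sample_nyha_matrix": self.settings.sample_nyha_matrix,
                "dirichlet_concentration": self.settings.dirichlet_concentration,
            },
            "parameter_specs": [
                {
                    "path": s.path,
                    "low": s.low,
                    "high": s.high,
                    "distribution": s.distribution,
                }
                for s in self.parameter_specs
            ],
        }

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ParameterSet) and self.to_dict() == other.to_dict()


def _traverse(pset: ParameterSet, path: str, set_value: tuple[Any] | None) -> Any:
    """Resolve a dotted parameter path; optionally assign a new value."""
    parts = path.split(".")
    err = ConfigError(f"unknown parameter path {path!r}")

    def leaf(obj: Any, attr: str) -> Any:
        if not hasattr(obj, attr):
            raise err
        if set_value is not None:
            object.__setattr__(obj, attr, set_value[0])
        return getattr(obj, attr)

    if parts[0] == "arms" and len(parts) == 3:
        if parts[1] not in pset.arms:
            raise err
        return leaf(pset.arms[parts[1]], parts[2])
    if parts[0] == "costs" and len(parts) == 2:
        return leaf(pset.costs, parts[1])
    if path == "readmit_per_hosp":
        if set_value is not None:
            pset.readmit_per_hosp = set_value[0]
        return pset.readmit_per_hosp
    if parts[0] == "utilities" and len(parts) == 2:
        if parts[1] == "event_disutility":
            if set_value is not None:
                object.__setattr__(pset.utilities, "event_disutility", set_value[0])
            return pset.utilities.event_disutility
        if parts[1] not in pset.utilities.per_cycle_utility:
            raise err
        if set_value is not None:
            d = dict(pset.utilities.per_cycle_utility)
            d[parts[1]] = set_value[0]
            object.__setattr__(pset.utilities, "per_cycle_utility", d)
        return pset.utilities.per_cycle_utility[parts[1]]
    if parts[0] == "settings" and len(parts) == 2:
        if not hasattr(pset.settings, parts[1]):
            raise err
        if set_value is not None:
            pset.settings = replace(pset.settings, **{parts[1]: set_value[0]})
        return getattr(pset.settings, parts[1])
    if parts[0] == "nyha_matrix" and len(parts) == 2 and parts[1].startswith("row"):
        i = int(parts[1][3:]) - 1
        if not 0 <= i < 4:
            raise err
        if set_value is not None:
            rows = pset.nyha_matrix.rows.copy()
            rows[i] = np.asarray(set_value[0], dtype=float)
            pset.nyha_matrix = NYHATransitionMatrix(rows)
        return pset.nyha_matrix.rows[i].copy()
    raise err


# ---------------------------------------------------------------------------
# Defaults and config loading
# ---------------------------------------------------------------------------


def _default_dict() -> dict[str, Any]:
    ref = importlib.resources.files("hfcea.data").joinpath("defaults.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, Mapping):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def _from_dict(raw: Mapping[str, Any]) -> ParameterSet:
    try:
        arms = {
            name: _ArmRates(
                cv_death_per_cycle=float(a["cv_death_per_cycle"]),
                hosp_per_cycle=float(a["hosp_per_cycle"]),
                drug_cost_per_cycle=float(a["drug_cost_per_cycle"]),
            )
            for name, a in raw["arms"].items()
        }
        costs = _SharedCosts(
            standard_per_cycle=float(raw["costs"]["standard_per_cycle"]),
            hosp_per_event=float(raw["costs"]["hosp_per_event"]),
        )
        util_raw = dict(raw["utilities"])
        event_dis = float(util_raw.pop("event_disutility"))
        settings_raw = dict(raw["settings"])
        settings_raw["initial_distribution"] = tuple(
            float(x) for x in settings_raw["initial_distribution"]
        )
        specs = []
        for s in raw.get("parameter_specs", []):
            specs.append(
                ParameterSpec(
                    path=s["path"],
                    mean=float("nan"),  # filled below from the live value
                    low=float(s["low"]),
                    high=float(s["high"]),
                    distribution=s["distribution"],
                )
            )
        pset = ParameterSet(
            arms=arms,
            readmit_per_hosp=float(raw["readmit_per_hosp"]),
            costs=costs,
            nyha_matrix=NYHATransitionMatrix(raw["nyha_matrix"]),
            noncv_mortality=AgeMortalityTable(
                tuple(
                    (float(b["age_low"]), float(b["age_high"]), float(b["prob"]))
                    for b in raw["noncv_mortality"]
                )
            ),
            utilities=UtilityInputs(util_raw, event_dis),
            settings=ModelSettings(**settings_raw),
            parameter_specs=specs,
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed config: {exc}") from exc
    # resolve spec means against the live parameter values
    pset.parameter_specs = [
        replace(s, mean=float(pset.get_param(s.path))) for s in specs
    ]
    pset.utilities.validate(strict_monotone=True)
    return pset.validate()


def paper_default_params() -> ParameterSet:
    """Return the bundled default parameter set (published base-case inputs)."""
    return _from_dict(_default_dict())


def load_config(path: str) -> ParameterSet:
    """Load a YAML/JSON config; omitted fields fall back to the defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if not text.strip():
        user: dict = {}
    elif str(path).endswith(".json"):
        user = json.loads(text)
    else:
        user = yaml.safe_load(text) or {}
    if not isinstance(user, Mapping):
        raise ConfigError(f"config {path}: top level must be a mapping")
    return _from_dict(_deep_merge(_default_dict(), user))
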