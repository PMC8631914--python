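"""One-way, scenario, and probabilistic sensitivity analyses.

OWSA perturbs each declared parameter to its low and high bound with all
other inputs at base case, recording the ICER at each bound and the spread
(tornado ordering). Scenario analysis reruns the deterministic model under
named override sets (hospital cost levels, time horizons, or user-supplied
transition inputs such as diabetes subgroups). The PSA samples every
uncertain parameter from its fitted distribution — Beta for probabilities
and utilities, Gamma for costs, Dirichlet for NYHA transition rows — reruns
the pair per draw, and summarizes the incremental cost/QALY cloud as
cost-effectiveness acceptability curves.

Ranges are treated as 95% confidence intervals when fitting distributions:
sd = (high - low) / (2 * 1.96), then method-of-moments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cea import CEAResult, accumulate, compare
from .engine import run_cohort
from .params import ConfigError, ParameterSet, ParameterSpec

__all__ = [
    "TornadoEntry",
    "ScenarioSpec",
    "PSAResult",
    "BUILTIN_SCENARIOS",
    "owsa",
    "run_scenario",
    "fit_beta",
    "fit_gamma",
    "fit_dirichlet",
    "run_psa",
    "ceac",
    "evaluate_pair",
]

_Z95 = 2.0 * 1.96  # 95% CI span in standard deviations


def evaluate_pair(params: ParameterSet, pair: str) -> CEAResult:
    """Deterministic model run for one trial-matched strategy pair."""
    intervention, control = params.pair(pair)
    totals = {}
    for name in (intervention, control):
        trace = run_cohort(params, name)
        totals[name] = accumulate(
            trace, params.strategy(name), params.utilities, params.settings
        )
    return compare(
        intervention, control, totals[intervention], totals[control], params.settings
    )


# ---------------------------------------------------------------------------
# One-way sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TornadoEntry:
    """ICER at a parameter's low/high bound, all other inputs at base case."""

    path: str
    low: float
    high: float
    icer_at_low: float | None
    icer_at_high: float | None
    tag_at_low: str | None
    tag_at_high: str | None
    invalid: bool = False
    invalid_reason: str = ""

    @property
    def spread(self) -> float:
        if self.icer_at_low is None or self.icer_at_high is None:
            return math.nan
        return abs(self.icer_at_high - self.icer_at_low)


def owsa(
    params: ParameterSet,
    pair: str,
    specs: Sequence[ParameterSpec] | None = None,
) -> list[TornadoEntry]:
    """One entry per parameter spec, sorted by descending ICER spread.

    A perturbation that violates a model invariant (probability above one,
    transition row not summing to one) flags the entry invalid rather than
    silently clamping the value.
    """
    if specs is None:
        specs = params.parameter_specs
    entries = []
    for spec in specs:
        results: dict[str, tuple[float | None, str | None]] = {}
        invalid_reason = ""
        for bound_name, bound in (("low", spec.low), ("high", spec.high)):
            try:
                perturbed = params.with_overrides({spec.path: bound})
                res = evaluate_pair(perturbed, pair)
                results[bound_name] = (res.icer, res.tag)
            except (ConfigError, ValueError) as exc:
                results[bound_name] = (None, "invalid")
                invalid_reason = f"{bound_name} bound: {exc}"
        entries.append(
            TornadoEntry(
                path=spec.path,
                low=spec.low,
                high=spec.high,
                icer_at_low=results["low"][0],
                icer_at_high=results["high"][0],
                tag_at_low=results["low"][1],
                tag_at_high=results["high"][1],
                invalid=bool(invalid_reason),
                invalid_reason=invalid_reason,
            )
        )
    return sorted(
        entries,
        key=lambda e: (-(e.spread if not math.isnan(e.spread) else -math.inf), e.path),
    )


def owsa_to_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.path for e in entries],
            "low": [e.low for e in entries],
            "high": [e.high for e in entries],
            "icer_at_low": [e.icer_at_low for e in entries],
            "icer_at_high": [e.icer_at_high for e in entries],
            "spread": [e.spread for e in entries],
            "invalid": [e.invalid for e in entries],
        }
    )


# ---------------------------------------------------------------------------
# Scenario analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioSpec:
    """A labelled set of parameter-path overrides for a deterministic rerun."""

    label: str
    overrides: Mapping[str, object] = field(default_factory=dict)


#: Published scenario grid: hospitalization cost by hospital level, and the
#: model time horizon. The diabetes-status scenario ships as a template only —
#: its subgroup transition probabilities are not published and must be supplied
#: by the user as overrides.
BUILTIN_SCENARIOS: dict[str, ScenarioSpec] = {
    "base": ScenarioSpec("base", {}),
    "hosp_cost_town": ScenarioSpec("hosp_cost_town", {"costs.hosp_per_event": 964.07}),
    "hosp_cost_county": ScenarioSpec(
        "hosp_cost_county", {"costs.hosp_per_event": 1120.75}
    ),
    "hosp_cost_municipal": ScenarioSpec(
        "hosp_cost_municipal", {"costs.hosp_per_event": 1785.36}
    ),
    "hosp_cost_provincial": ScenarioSpec(
        "hosp_cost_provincial", {"costs.hosp_per_event": 2812.51}
    ),
    "hosp_cost_ministerial": ScenarioSpec(
        "hosp_cost_ministerial", {"costs.hosp_per_event": 3209.47}
    ),
    "horizon_5": ScenarioSpec("horizon_5", {"settings.horizon_years": 5.0}),
    "horizon_10": ScenarioSpec("horizon_10", {"settings.horizon_years": 10.0}),
    "horizon_15": ScenarioSpec("horizon_15", {"settings.horizon_years": 15.0}),
    "horizon_20": ScenarioSpec("horizon_20", {"settings.horizon_years": 20.0}),
    # Template: supply arm-level event probabilities for the diabetic /
    # non-diabetic subgroup, e.g. {"arms.dapagliflozin.cv_death_per_cycle": ...}
    "diabetes_template": ScenarioSpec("diabetes_template", {}),
}


def run_scenario(params: ParameterSet, spec: ScenarioSpec, pair: str) -> CEAResult:
    """Deterministic rerun under merged overrides; base parameters untouched."""
    return evaluate_pair(params.with_overrides(spec.overrides), pair)


# ---------------------------------------------------------------------------
# Distribution fitting (method of moments, range read as a 95% CI)
# ---------------------------------------------------------------------------


def _range_sd(low: float, high: float) -> float:
    return (high - low) / _Z95


def fit_beta(mean: float, low: float, high: float) -> tuple[float, float] | None:
    """Method-of-moments Beta(alpha, beta); ``None`` for a degenerate range.

    Raises when the implied variance is not attainable by a Beta distribution
    with the requested mean.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean {mean} outside (0, 1)")
    sd = _range_sd(low, high)
    if sd == 0.0:
        return None  # fixed parameter (zero variance)
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ValueError(
            f"implied variance {var:.3g} >= mean(1-mean) {mean * (1 - mean):.3g}; "
            "no Beta distribution matches these moments"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def fit_gamma(mean: float, low: float, high: float) -> tuple[float, float] | None:
    """Method-of-moments Gamma as (shape, scale); ``None`` when degenerate."""
    if mean <= 0:
        raise ValueError(f"gamma mean {mean} must be positive")
    sd = _range_sd(low, high)
    if sd == 0.0:
        return None
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return shape, scale


def fit_dirichlet(row: Sequence[float], concentration: float = 1000.0) -> np.ndarray:
    """Dirichlet concentration vector ``row * concentration`` for one NYHA row."""
    row = np.asarray(row, dtype=float)
    if abs(row.sum() - 1.0) > 1e-9:
        raise ValueError(f"row sums to {row.sum()}, not 1")
    return row * concentration


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSAResult:
    """Per-draw incremental (cost, QALY) pairs from a seeded Monte Carlo PSA."""

    pair: str
    seed: int
    n_draws: int
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    sampled: pd.DataFrame  # one row per draw, one column per sampled path

    def probability_ce(self, wtp: float) -> float:
        """Fraction of draws with positive net monetary benefit at ``wtp``."""
        return float(np.mean(wtp * self.delta_qaly - self.delta_cost > 0.0))

    def ceac(self, wtp_grid: Sequence[float]) -> pd.DataFrame:
        return ceac(self, wtp_grid)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "draw": np.arange(self.n_draws),
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_qaly,
            }
        )
        return df


def _sample_value(
    spec: ParameterSpec, rng: np.random.Generator
) -> float:
    """Draw one value for a scalar spec (sign-aware for negative utilities)."""
    mean, low, high = spec.mean, spec.low, spec.high
    if spec.distribution == "fixed" or spec.is_degenerate:
        return mean
    if spec.distribution == "beta":
        if mean < 0:
            # disutility: fit the Beta on the magnitude, then negate
            fit = fit_beta(-mean, -high, -low)
            if fit is None:
                return mean
            return -float(rng.beta(*fit))
        fit = fit_beta(mean, low, high)
        if fit is None:
            return mean
        return float(rng.beta(*fit))
    if spec.distribution == "gamma":
        fit = fit_gamma(mean, low, high)
        if fit is None:
            return mean
        shape, scale = fit
        return float(rng.gamma(shape, scale))
    raise ValueError(f"cannot sample distribution {spec.distribution!r}")


def _sample_nyha_rows(
    params: ParameterSet, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Jointly sample each NYHA row from a Dirichlet, keeping structural zeros."""
    conc = params.settings.dirichlet_concentration
    out = {}
    for i in range(4):
        row = params.nyha_matrix.rows[i]
        alpha = fit_dirichlet(row, conc)
        nz = alpha > 0.0
        draw = np.zeros(4)
        draw[nz] = rng.dirichlet(alpha[nz])
        out[f"nyha_matrix.row{i + 1}"] = draw
    return out


def sample_parameter_set(
    params: ParameterSet, rng: np.random.Generator
) -> tuple[ParameterSet, dict[str, object]]:
    """One PSA draw: a perturbed copy of ``params`` plus the sampled values."""
    overrides: dict[str, object] = {}
    for spec in params.parameter_specs:
        overrides[spec.path] = _sample_value(spec, rng)
    if params.settings.sample_nyha_matrix:
        overrides.update(_sample_nyha_rows(params, rng))
    return params.with_overrides(overrides), overrides


def run_psa(
    params: ParameterSet,
    pair: str,
    n_draws: int = 1000,
    seed: int = 0,
) -> PSAResult:
    """Seeded Monte Carlo PSA for one strategy pair.

    Each draw independently samples every declared uncertain parameter (and,
    unless disabled, the NYHA transition rows), reruns both arms and records
    the incremental discounted cost and QALYs. Output is reproducible
    bit-for-bit for a given seed.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    d_cost = np.empty(n_draws)
    d_qaly = np.empty(n_draws)
    rows = []
    for j in range(n_draws):
        drawn, overrides = sample_parameter_set(params, rng)
        res = evaluate_pair(drawn, pair)
        d_cost[j] = res.incremental_cost
        d_qaly[j] = res.incremental_qaly
        rows.append(
            {
                k: (float(v) if np.isscalar(v) else list(np.asarray(v)))
                for k, v in overrides.items()
            }
        )
    sampled = pd.DataFrame(rows)
    return PSAResult(
        pair=pair,
        seed=seed,
        n_draws=n_draws,
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        sampled=sampled,
    )


def ceac(psa: PSAResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Pointwise acceptability curve: P(NMB > 0) at each willingness-to-pay."""
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    if np.any(wtp_grid < 0):
        raise ValueError("wtp_grid values must be non-negative")
    probs = [psa.probability_ce(w) for w in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "probability_ce": probs})
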