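"""Cohort state-transition engine.

Builds the 6x6 per-cycle transition matrix (four NYHA classes plus two
absorbing death states) and iterates the cohort distribution over quarterly
cycles, recording state occupancy and expected hospitalization, readmission
and death counts per initial patient.

Within a cycle, cause-specific death probabilities apply first (additively:
the arm-level cardiovascular probability plus the age-band non-cardiovascular
probability) and the NYHA redistribution applies to the survivors.
Hospitalization is an event overlaid on the state process: it does not move
patients between NYHA classes, and the at-risk population is the alive
fraction at the start of the cycle. Each hospitalization carries a fixed
readmission probability within the same cycle, applied once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import (
    AgeMortalityTable,
    HealthState,
    NYHATransitionMatrix,
    ParameterSet,
    StrategyParams,
)
from .rates import annual_prob_to_cycle

__all__ = [
    "N_STATES",
    "IDX_DEAD_CV",
    "IDX_DEAD_NONCV",
    "CohortTrace",
    "build_cycle_matrix",
    "run_cohort",
    "survival_curve",
    "median_survival",
    "cumulative_event_rates",
]

N_STATES = 6
IDX_DEAD_CV = HealthState.DEAD_CV.value
IDX_DEAD_NONCV = HealthState.DEAD_NONCV.value

_STOCHASTIC_TOL = 1e-12


def build_cycle_matrix(
    strategy: StrategyParams,
    nyha: NYHATransitionMatrix,
    mortality: AgeMortalityTable,
    age: float,
    *,
    cycle_length_years: float = 0.25,
    noncv_is_annual: bool = False,
) -> np.ndarray:
    """Assemble the 6x6 transition matrix for one cycle at attained ``age``.

    For each NYHA row i: P(i -> DEAD_CV) = p_cv, P(i -> DEAD_NONCV) =
    p_noncv(age), and P(i -> NYHA j) = (1 - p_cv - p_noncv) * nyha[i][j].
    Death rows are identity.
    """
    p_cv = strategy.cv_death_per_cycle
    p_ncv = mortality.lookup(age)
    if noncv_is_annual:
        p_ncv = annual_prob_to_cycle(p_ncv, cycle_length_years)
    if p_cv + p_ncv > 1.0:
        raise ValueError(
            f"death probabilities exceed 1 at age {age}: cv={p_cv}, noncv={p_ncv}"
        )
    survive = 1.0 - p_cv - p_ncv
    mat = np.zeros((N_STATES, N_STATES))
    mat[:4, :4] = survive * nyha.rows
    mat[:4, IDX_DEAD_CV] = p_cv
    mat[:4, IDX_DEAD_NONCV] = p_ncv
    mat[IDX_DEAD_CV, IDX_DEAD_CV] = 1.0
    mat[IDX_DEAD_NONCV, IDX_DEAD_NONCV] = 1.0
    assert np.all(np.abs(mat.sum(axis=1) - 1.0) <= _STOCHASTIC_TOL)
    return mat


@dataclass(frozen=True)
class CohortTrace:
    """Cycle-by-cycle cohort trajectory for one strategy.

    ``occupancy`` has shape (n_cycles + 1, 6): row k is the state distribution
    at the k-th cycle boundary (row 0 is the initial distribution). Event
    arrays have length n_cycles: entry k is the expected count per initial
    patient during cycle k.
    """

    strategy_name: str
    cycle_length_years: float
    start_age: float
    occupancy: np.ndarray
    expected_hospitalizations: np.ndarray
    expected_readmissions: np.ndarray
    expected_cv_deaths: np.ndarray
    expected_noncv_deaths: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def times(self) -> np.ndarray:
        """Cycle-boundary times in years (length n_cycles + 1)."""
        return np.arange(self.n_cycles + 1) * self.cycle_length_years

    @property
    def ages(self) -> np.ndarray:
        return self.start_age + self.times

    def alive(self) -> np.ndarray:
        """Alive fraction at each cycle boundary."""
        return 1.0 - self.occupancy[:, IDX_DEAD_CV] - self.occupancy[:, IDX_DEAD_NONCV]

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy per-boundary export (events attributed to the cycle they end)."""
        n = self.n_cycles
        df = pd.DataFrame(self.occupancy, columns=[s.name for s in HealthState])
        df.insert(0, "strategy", self.strategy_name)
        df.insert(1, "cycle", np.arange(n + 1))
        df.insert(2, "time_years", self.times)
        df.insert(3, "age", self.ages)
        df["alive"] = self.alive()
        pad = lambda a: np.concatenate([[0.0], a])  # noqa: E731 - boundary 0 has no prior cycle
        df["expected_hospitalizations"] = pad(self.expected_hospitalizations)
        df["expected_readmissions"] = pad(self.expected_readmissions)
        df["expected_cv_deaths"] = pad(self.expected_cv_deaths)
        df["expected_noncv_deaths"] = pad(self.expected_noncv_deaths)
        return df


def run_cohort(
    params: ParameterSet,
    strategy_name: str,
    horizon_years: float | None = None,
) -> CohortTrace:
    """Iterate the cohort over the horizon for one strategy.

    The cohort starts distributed over NYHA classes per the configured initial
    distribution; age advances one cycle length per cycle and selects the
    non-cardiovascular mortality band by attained age at the cycle start.
    """
    strategy = params.strategy(strategy_name)
    s = params.settings
    if horizon_years is None:
        horizon_years = s.horizon_years
    n_ratio = horizon_years / s.cycle_length_years
    if horizon_years < 0 or abs(n_ratio - round(n_ratio)) > 1e-9:
        raise ValueError(
            f"horizon {horizon_years} is not a multiple of the cycle length"
        )
    n_cycles = int(round(n_ratio))

    occ = np.zeros((n_cycles + 1, N_STATES))
    occ[0, :4] = np.asarray(s.initial_distribution, dtype=float)
    exp_hosp = np.zeros(n_cycles)
    exp_readmit = np.zeros(n_cycles)
    exp_cv = np.zeros(n_cycles)
    exp_ncv = np.zeros(n_cycles)

    for k in range(n_cycles):
        age = s.start_age + k * s.cycle_length_years
        mat = build_cycle_matrix(
            strategy,
            params.nyha_matrix,
            params.noncv_mortality,
            age,
            cycle_length_years=s.cycle_length_years,
            noncv_is_annual=s.noncv_mortality_is_annual,
        )
        occ[k + 1] = occ[k] @ mat
        alive_start = 1.0 - occ[k, IDX_DEAD_CV] - occ[k, IDX_DEAD_NONCV]
        exp_hosp[k] = alive_start * strategy.hosp_per_cycle
        exp_readmit[k] = exp_hosp[k] * strategy.readmit_per_hosp
        exp_cv[k] = occ[k + 1, IDX_DEAD_CV] - occ[k, IDX_DEAD_CV]
        exp_ncv[k] = occ[k + 1, IDX_DEAD_NONCV] - occ[k, IDX_DEAD_NONCV]

    return CohortTrace(
        strategy_name=strategy_name,
        cycle_length_years=s.cycle_length_years,
        start_age=s.start_age,
        occupancy=occ,
        expected_hospitalizations=exp_hosp,
        expected_readmissions=exp_readmit,
        expected_cv_deaths=exp_cv,
        expected_noncv_deaths=exp_ncv,
    )


def survival_curve(trace: CohortTrace) -> np.ndarray:
    """(time in years, alive fraction) at each cycle boundary; shape (n+1, 2)."""
    return np.column_stack([trace.times, trace.alive()])


def median_survival(trace: CohortTrace) -> float:
    """First cycle-boundary time at which the alive fraction is <= 0.5.

    Returns ``math.inf`` when the alive fraction stays above 0.5 over the whole
    horizon (censored: median survival exceeds the horizon).
    """
    alive = trace.alive()
    below = np.nonzero(alive <= 0.5)[0]
    if below.size == 0:
        return math.inf
    return float(below[0] * trace.cycle_length_years)


def cumulative_event_rates(trace: CohortTrace, at_months: float) -> tuple[float, float, float]:
    """(all-cause mortality %, CV mortality %, HF-hospitalization %) at a time.

    Mortality figures are cumulative death-state occupancies; the
    hospitalization figure is the cumulative expected number of
    hospitalization events per initial patient (readmissions not included),
    all expressed as percentages of the initial cohort.
    """
    cycles = at_months / (trace.cycle_length_years * 12.0)
    if abs(cycles - round(cycles)) > 1e-9:
        raise ValueError(f"{at_months} months is not a whole number of cycles")
    k = int(round(cycles))
    if not 0 <= k <= trace.n_cycles:
        raise ValueError(f"{at_months} months is beyond the simulated horizon")
    dead_cv = trace.occupancy[k, IDX_DEAD_CV]
    dead_ncv = trace.occupancy[k, IDX_DEAD_NONCV]
    hosp = float(trace.expected_hospitalizations[:k].sum())
    return (100.0 * (dead_cv + dead_ncv), 100.0 * dead_cv, 100.0 * hosp)
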