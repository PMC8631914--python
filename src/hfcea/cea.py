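"""Discounted cost/QALY accumulation and incremental cost-effectiveness.

Costs and QALYs are accumulated cycle by cycle over a cohort trace. State
terms (treatment costs, per-cycle state utilities) use half-cycle-corrected
occupancy (the mean of the start- and end-of-cycle distributions) by default,
so that a patient dying during a cycle contributes half a cycle of person-
time. Event terms (hospitalization/readmission costs and the one-off -0.1
QALY decrement) are counted in full in the cycle they occur. Monetary terms
are discounted at the configured annual rate; under the default ``mid_cycle``
convention cycle k is discounted to time (k + 0.5) cycle lengths. The event
QALY decrements are applied as undiscounted tolls by default
(``discount_event_disutility = false``), the convention that reproduces the
published base-case totals; setting the flag discounts them like every other
QALY term.

Cost-effectiveness verdicts follow the WHO GDP-multiple convention: an ICER
under 1x GDP per capita is "very cost-effective", between 1x and 3x
"cost-effective", above 3x "not cost-effective"; strategies that are cheaper
and more effective (or the reverse) are dominant/dominated and no ICER is
reported as a number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import CohortTrace, IDX_DEAD_CV, IDX_DEAD_NONCV
from .params import ModelSettings, StrategyParams, UtilityInputs
from .rates import discount_factor

__all__ = ["CEAResult", "accumulate", "compare"]


@dataclass(frozen=True)
class CEAResult:
    """Totals for an intervention/control pair and the incremental verdict."""

    intervention: str
    control: str
    intervention_cost: float
    intervention_qaly: float
    control_cost: float
    control_qaly: float
    incremental_cost: float
    incremental_qaly: float
    icer: float | None  # None when a dominance/equality tag applies
    tag: str | None  # dominant | dominated | no difference | extended dominance
    nmb_at_wtp: float
    ce_category: str

    def icer_label(self) -> str:
        return self.tag if self.icer is None else f"{self.icer:,.2f}"


def _discount_times(n_cycles: int, settings: ModelSettings) -> tuple[np.ndarray, np.ndarray]:
    """Discount times (years) for state and event terms of each cycle."""
    k = np.arange(n_cycles)
    dt = settings.cycle_length_years
    if settings.discount_convention == "mid_cycle":
        t = (k + 0.5) * dt
    else:
        t = k * dt
    return t, t  # events share the convention's time point


def accumulate(
    trace: CohortTrace,
    strategy: StrategyParams,
    utilities: UtilityInputs,
    settings: ModelSettings,
) -> tuple[float, float]:
    """Return (discounted total cost, discounted total QALYs) for one arm."""
    if abs(trace.cycle_length_years - settings.cycle_length_years) > 1e-12:
        raise ValueError("trace cycle length does not match the settings")
    n = trace.n_cycles
    occ = trace.occupancy
    if settings.half_cycle_correction:
        occ_eff = 0.5 * (occ[:-1] + occ[1:])
    else:
        occ_eff = occ[:-1]
    alive_eff = 1.0 - occ_eff[:, IDX_DEAD_CV] - occ_eff[:, IDX_DEAD_NONCV]

    t_state, t_event = _discount_times(n, settings)
    df_state = discount_factor(t_state, settings.annual_discount)
    df_event = discount_factor(t_event, settings.annual_discount)

    events = trace.expected_hospitalizations + trace.expected_readmissions
    per_cycle_cost = strategy.standard_cost_per_cycle + strategy.drug_cost_per_cycle

    state_cost = alive_eff * per_cycle_cost
    event_cost = events * strategy.hosp_cost_per_event
    state_qaly = occ_eff @ utilities.as_vector()
    event_qaly = events * utilities.event_disutility
    df_toll = df_event if settings.discount_event_disutility else 1.0

    total_cost = float(np.sum(state_cost * df_state) + np.sum(event_cost * df_event))
    total_qaly = float(np.sum(state_qaly * df_state) + np.sum(event_qaly * df_toll))
    return total_cost, total_qaly


def compare(
    intervention: str,
    control: str,
    intervention_totals: tuple[float, float],
    control_totals: tuple[float, float],
    settings: ModelSettings,
) -> CEAResult:
    """Incremental comparison of two arms evaluated under identical settings."""
    ci, qi = intervention_totals
    cc, qc = control_totals
    d_cost = ci - cc
    d_qaly = qi - qc
    nmb = settings.wtp_per_qaly * d_qaly - d_cost

    icer: float | None = None
    tag: str | None = None
    if abs(d_cost) < 1e-12 and abs(d_qaly) < 1e-12:
        tag = "no difference"
        category = "no difference"
    elif d_qaly > 0 and d_cost <= 0:
        tag = "dominant"
        category = "dominant"
    elif d_qaly <= 0 and d_cost >= 0:
        tag = "dominated"
        category = "dominated"
    elif d_qaly < 0 and d_cost < 0:
        # cheaper but less effective: report the south-west ICER as a tag-free
        # ratio is misleading; tag it and let NMB carry the verdict
        tag = "less effective, cheaper"
        category = "southwest"
    else:
        icer = d_cost / d_qaly
        gdp = settings.gdp_per_capita
        if icer < gdp:
            category = "very_cost_effective"
        elif icer <= 3.0 * gdp:
            category = "cost_effective"
        else:
            category = "not_cost_effective"

    return CEAResult(
        intervention=intervention,
        control=control,
        intervention_cost=ci,
        intervention_qaly=qi,
        control_cost=cc,
        control_qaly=qc,
        incremental_cost=d_cost,
        incremental_qaly=d_qaly,
        icer=icer,
        tag=tag,
        nmb_at_wtp=nmb,
        ce_category=category,
    )
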