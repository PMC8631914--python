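"""Rate, probability, discount and currency conversions.

Trial publications report cumulative event proportions over a follow-up window;
the Markov model needs per-cycle transition probabilities. Under a constant
hazard (the declining-exponential / DEALE approximation) the conversion is

    r = -ln(S) / t        (S = 1 - event proportion, t = follow-up in cycles)
    P = 1 - exp(-r)       (probability per cycle)

All functions here are pure; no file I/O.
"""

from __future__ import annotations

import math

import numpy as np
from dataclasses import dataclass

__all__ = [
    "TrialOutcomeRate",
    "prob_per_cycle",
    "annual_prob_to_cycle",
    "discount_factor",
    "inflate_cost",
    "cny_to_usd",
    "CNY_PER_USD",
]

#: 2020 exchange rate used to convert all CNY-denominated costs.
CNY_PER_USD = 6.44


@dataclass(frozen=True)
class TrialOutcomeRate:
    """Cumulative event proportion over a trial's follow-up window."""

    event_proportion: float  # fraction of the cohort with >= 1 event
    followup_months: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.event_proportion < 1.0:
            raise ValueError(
                f"event_proportion {self.event_proportion} outside [0, 1) "
                "(a proportion of 1 implies an infinite hazard)"
            )
        if self.followup_months <= 0:
            raise ValueError("followup_months must be positive")


def prob_per_cycle(rate: TrialOutcomeRate, cycle_length_months: float = 3.0) -> float:
    """Convert a cumulative trial event proportion to a per-cycle probability.

    The hazard is assumed constant over follow-up: the surviving (event-free)
    fraction ``S = 1 - event_proportion`` observed over ``t`` cycles implies a
    per-cycle rate ``r = -ln(S)/t``, hence per-cycle probability ``1 - e^-r``.
    """
    if cycle_length_months <= 0:
        raise ValueError("cycle_length_months must be positive")
    t_cycles = rate.followup_months / cycle_length_months
    r = -math.log(1.0 - rate.event_proportion) / t_cycles
    return 1.0 - math.exp(-r)


def annual_prob_to_cycle(p_annual: float, cycle_length_years: float) -> float:
    """Constant-hazard rescaling of an annual probability to one cycle."""
    if not 0.0 <= p_annual < 1.0:
        raise ValueError(f"p_annual {p_annual} outside [0, 1)")
    return 1.0 - (1.0 - p_annual) ** cycle_length_years


def discount_factor(time_years, annual_rate: float):
    """Present-value factor ``(1 + rate)^-t`` for a payoff at ``t`` years.

    Accepts a scalar or an array of times.
    """
    time_years = np.asarray(time_years, dtype=float)
    if np.any(time_years < 0):
        raise ValueError("time_years must be >= 0")
    if annual_rate < 0:
        raise ValueError("annual_rate must be >= 0")
    out = (1.0 + annual_rate) ** (-time_years)
    return float(out) if out.ndim == 0 else out


def inflate_cost(amount: float, annual_rate: float, years: float) -> float:
    """Compound a cost forward: ``amount * (1 + rate)^years``."""
    if amount < 0:
        raise ValueError("amount must be >= 0")
    return amount * (1.0 + annual_rate) ** years


def cny_to_usd(amount_cny: float) -> float:
    """Convert CNY to USD at the fixed 6.44 CNY/USD rate."""
    return amount_cny / CNY_PER_USD
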