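"""Model/Results facade over the cohort engine and analysis modules.

``MarkovCEA`` bundles a parameter set with a trial-matched strategy pair;
``fit()`` evaluates the deterministic cohort model for both arms and returns
a ``CEAResults`` object carrying the traces, discounted totals, incremental
statistics and validation diagnostics, with ``summary()``, sensitivity
analyses and plotting hanging off it.

    >>> res = MarkovCEA.paper_defaults(pair="dapa").fit()
    >>> res.icer          # doctest: +SKIP
    5603.9...
    >>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import sensitivity as sens
from .cea import CEAResult, accumulate, compare
from .engine import CohortTrace, cumulative_event_rates, median_survival, run_cohort
from .params import ParameterSet, load_config, paper_default_params

__all__ = ["MarkovCEA", "CEAResults"]


class MarkovCEA:
    """Cost-utility Markov model for one SGLT2-inhibitor/control pair.

    Parameters
    ----------
    params
        Full model input set (defaults to the published base case).
    pair
        ``"dapa"`` (dapagliflozin vs control 1) or ``"empa"``
        (empagliflozin vs control 2).
    """

    def __init__(self, params: ParameterSet, pair: str = "dapa"):
        params.pair(pair)  # raises on unknown pair
        self.params = params
        self.pair = pair

    @classmethod
    def paper_defaults(cls, pair: str = "dapa") -> "MarkovCEA":
        """Model under the published base-case inputs."""
        return cls(paper_default_params(), pair=pair)

    @classmethod
    def from_config(cls, path: str, pair: str = "dapa") -> "MarkovCEA":
        """Model from a YAML/JSON config; omitted fields use the defaults."""
        return cls(load_config(path), pair=pair)

    @property
    def intervention(self) -> str:
        return self.params.pair(self.pair)[0]

    @property
    def control(self) -> str:
        return self.params.pair(self.pair)[1]

    def fit(self) -> "CEAResults":
        """Run both arms over the horizon and assemble the results object."""
        traces = {}
        totals = {}
        for name in self.params.pair(self.pair):
            trace = run_cohort(self.params, name)
            traces[name] = trace
            totals[name] = accumulate(
                trace, self.params.strategy(name), self.params.utilities,
                self.params.settings,
            )
        result = compare(
            self.intervention,
            self.control,
            totals[self.intervention],
            totals[self.control],
            self.params.settings,
        )
        return CEAResults(model=self, traces=traces, result=result)


@dataclass
class CEAResults:
    """Fitted base-case results with sensitivity analyses and diagnostics."""

    model: MarkovCEA
    traces: Mapping[str, CohortTrace]
    result: CEAResult

    # -- point estimates --------------------------------------------------

    @property
    def icer(self) -> float | None:
        return self.result.icer

    @property
    def incremental_cost(self) -> float:
        return self.result.incremental_cost

    @property
    def incremental_qaly(self) -> float:
        return self.result.incremental_qaly

    @property
    def nmb(self) -> float:
        return self.result.nmb_at_wtp

    def totals_frame(self) -> pd.DataFrame:
        """Base-case table: totals, incrementals and the ICER per arm."""
        r = self.result
        rows = [
            {
                "strategy": r.intervention,
                "total_cost": r.intervention_cost,
                "total_qaly": r.intervention_qaly,
                "incremental_cost": r.incremental_cost,
                "incremental_qaly": r.incremental_qaly,
                "icer": r.icer if r.icer is not None else np.nan,
                "tag": r.tag or "",
            },
            {
                "strategy": r.control,
                "total_cost": r.control_cost,
                "total_qaly": r.control_qaly,
                "incremental_cost": np.nan,
                "incremental_qaly": np.nan,
                "icer": np.nan,
                "tag": "",
            },
        ]
        return pd.DataFrame(rows)

    # -- validation diagnostics -------------------------------------------

    def validation(self) -> pd.DataFrame:
        """Median survival and cumulative event rates per arm.

        Event rates are evaluated at the closest whole-cycle time to each
        source trial's follow-up (18 months for the dapagliflozin trial,
        15 months for the 16-month empagliflozin trial).
        """
        at_months = 18.0 if self.model.pair == "dapa" else 15.0
        rows = []
        for name, trace in self.traces.items():
            allc, cv, hosp = cumulative_event_rates(trace, at_months)
            rows.append(
                {
                    "strategy": name,
                    "median_survival_years": median_survival(trace),
                    "at_months": at_months,
                    "all_cause_mortality_pct": allc,
                    "cv_mortality_pct": cv,
                    "hf_hospitalization_pct": hosp,
                }
            )
        return pd.DataFrame(rows)

    # -- sensitivity analyses ----------------------------------------------

    def owsa(self) -> list[sens.TornadoEntry]:
        """One-way sensitivity analysis over every declared parameter range."""
        return sens.owsa(self.model.params, self.model.pair)

    def scenario(self, label_or_spec: str | sens.ScenarioSpec) -> CEAResult:
        """Deterministic rerun under a named or user-built scenario."""
        if isinstance(label_or_spec, str):
            try:
                spec = sens.BUILTIN_SCENARIOS[label_or_spec]
            except KeyError:
                raise KeyError(
                    f"unknown scenario {label_or_spec!r}; available: "
                    f"{sorted(sens.BUILTIN_SCENARIOS)}"
                ) from None
        else:
            spec = label_or_spec
        return sens.run_scenario(self.model.params, spec, self.model.pair)

    def psa(self, n_draws: int = 1000, seed: int = 0) -> sens.PSAResult:
        """Seeded probabilistic sensitivity analysis for this pair."""
        return sens.run_psa(self.model.params, self.model.pair, n_draws, seed)

    # -- plotting -----------------------------------------------------------

    def plot_tornado(self, ax=None, top: int = 12):
        from .plotting import plot_tornado

        return plot_tornado(self.owsa(), base_icer=self.icer, ax=ax, top=top)

    def plot_ceac(self, psa: sens.PSAResult | None = None, ax=None, **psa_kwargs):
        from .plotting import plot_ceac

        if psa is None:
            psa = self.psa(**psa_kwargs)
        return plot_ceac(psa, wtp_line=self.model.params.settings.wtp_per_qaly, ax=ax)

    def plot_ce_plane(self, psa: sens.PSAResult | None = None, ax=None, **psa_kwargs):
        from .plotting import plot_ce_plane

        if psa is None:
            psa = self.psa(**psa_kwargs)
        return plot_ce_plane(psa, wtp=self.model.params.settings.wtp_per_qaly, ax=ax)

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        """Human-readable base-case and validation summary table."""
        r = self.result
        s = self.model.params.settings
        lines = []
        w = 76
        lines.append("Markov cohort cost-utility analysis".center(w))
        lines.append("=" * w)
        lines.append(
            f"Pair: {r.intervention} vs {r.control}    "
            f"Horizon: {s.horizon_years:g} y ({s.n_cycles} cycles)    "
            f"Discount: {s.annual_discount:.0%}"
        )
        lines.append("-" * w)
        lines.append(f"{'strategy':<16}{'total cost ($)':>16}{'total QALYs':>14}")
        lines.append(
            f"{r.intervention:<16}{r.intervention_cost:>16,.2f}{r.intervention_qaly:>14.2f}"
        )
        lines.append(f"{r.control:<16}{r.control_cost:>16,.2f}{r.control_qaly:>14.2f}")
        lines.append("-" * w)
        lines.append(
            f"Incremental cost: ${r.incremental_cost:,.2f}    "
            f"Incremental QALYs: {r.incremental_qaly:.2f}"
        )
        lines.append(f"ICER: {r.icer_label()} $/QALY    category: {r.ce_category}")
        lines.append(f"NMB at WTP ${s.wtp_per_qaly:,.2f}/QALY: ${r.nmb_at_wtp:,.2f}")
        lines.append("-" * w)
        for _, row in self.validation().iterrows():
            med = row["median_survival_years"]
            med_s = f"{med:.2f} y" if np.isfinite(med) else "> horizon"
            lines.append(
                f"{row['strategy']:<16} median survival {med_s}; at "
                f"{row['at_months']:g} mo: all-cause death "
                f"{row['all_cause_mortality_pct']:.1f}%, CV death "
                f"{row['cv_mortality_pct']:.2f}%, HF hosp. "
                f"{row['hf_hospitalization_pct']:.1f}%"
            )
        lines.append("=" * w)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<CEAResults {self.result.intervention} vs {self.result.control}: "
            f"ICER {self.result.icer_label()}>"
        )
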