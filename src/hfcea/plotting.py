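"""Tornado, acceptability-curve and cost-effectiveness-plane figures."""

from __future__ import annotations

import math
from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)  # headless-safe default
import matplotlib.pyplot as plt
import numpy as np

from .sensitivity import PSAResult, TornadoEntry, ceac

__all__ = ["plot_tornado", "plot_ceac", "plot_ce_plane", "default_wtp_grid"]


def default_wtp_grid(wtp: float = 11008.07, n: int = 45) -> np.ndarray:
    """Willingness-to-pay grid from 0 to 3x the threshold."""
    return np.linspace(0.0, 3.0 * wtp, n)


def plot_tornado(
    entries: Sequence[TornadoEntry],
    base_icer: float | None = None,
    ax=None,
    top: int = 12,
):
    """Horizontal tornado diagram of ICER at each parameter's bounds."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    shown = [e for e in entries if not math.isnan(e.spread)][:top]
    shown = shown[::-1]  # widest bar on top
    ys = np.arange(len(shown))
    for y, e in zip(ys, shown):
        lo, hi = sorted((e.icer_at_low, e.icer_at_high))
        ax.barh(y, hi - lo, left=lo, height=0.6, color="#4878a8")
    ax.set_yticks(ys)
    ax.set_yticklabels([e.path for e in shown], fontsize=8)
    if base_icer is not None:
        ax.axvline(base_icer, color="k", lw=1, ls="--", label="base case")
        ax.legend(loc="lower right", fontsize=8)
    ax.set_xlabel("ICER ($ per QALY)")
    ax.set_title("One-way sensitivity analysis")
    ax.figure.tight_layout()
    return ax


def plot_ceac(psa: PSAResult, wtp_line: float | None = None, ax=None, wtp_grid=None):
    """Cost-effectiveness acceptability curve for one strategy pair."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    if wtp_grid is None:
        wtp_grid = default_wtp_grid(wtp_line or 11008.07)
    curve = ceac(psa, wtp_grid)
    ax.plot(curve["wtp"], curve["probability_ce"], lw=1.5)
    if wtp_line is not None:
        ax.axvline(wtp_line, color="k", lw=1, ls="--")
        ax.annotate(
            f"WTP ${wtp_line:,.0f}: {psa.probability_ce(wtp_line):.1%}",
            (wtp_line, psa.probability_ce(wtp_line)),
            textcoords="offset points",
            xytext=(6, -12),
            fontsize=8,
        )
    ax.set_xlabel("Willingness to pay ($ per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(f"CEAC ({psa.pair} pair, {psa.n_draws} draws)")
    ax.figure.tight_layout()
    return ax


def plot_ce_plane(psa: PSAResult, wtp: float | None = None, ax=None):
    """Incremental cost/QALY scatter with the willingness-to-pay line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(psa.delta_qaly, psa.delta_cost, s=6, alpha=0.4)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    if wtp is not None:
        xs = np.array(ax.get_xlim())
        ax.plot(xs, wtp * xs, "k--", lw=1, label=f"WTP ${wtp:,.0f}/QALY")
        ax.legend(fontsize=8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost ($)")
    ax.set_title(f"Cost-effectiveness plane ({psa.pair} pair)")
    ax.figure.tight_layout()
    return ax
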