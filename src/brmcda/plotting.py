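"""Standard benefit-risk figures: forest, tornado, density/CDF, temporal."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .montecarlo import density_outputs
from .sensitivity import OneWayResult, TemporalBR

__all__ = ["forest_plot", "tornado_plot", "density_plot", "temporal_plot"]


def forest_plot(table: pd.DataFrame, ax: plt.Axes | None = None) -> plt.Axes:
    """Excess events per 10 000 patient-years with 95% CIs, one row per endpoint."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.5 * len(table) + 1.5))
    y = np.arange(len(table))[::-1]
    ax.errorbar(table["delta"], y,
                xerr=[table["delta"] - table["ci_lo"],
                      table["ci_hi"] - table["delta"]],
                fmt="s", color="black", capsize=3)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels(table["endpoint"])
    ax.set_xlabel("excess events per 10 000 patient-years (active − control)")
    return ax


def tornado_plot(results: Sequence[OneWayResult],
                 ax: plt.Axes | None = None) -> plt.Axes:
    """One-way weight-sensitivity bars, widest first."""
    ordered = sorted(results, key=lambda r: r.bar_width, reverse=True)
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.5 * len(ordered) + 1.5))
    y = np.arange(len(ordered))[::-1]
    for yi, r in zip(y, ordered):
        lo, hi = sorted((r.delta_s_low, r.delta_s_high))
        ax.barh(yi, hi - lo, left=lo, color="steelblue", height=0.6)
    if ordered:
        ax.axvline(ordered[0].base, color="black", lw=1.2)
    ax.set_yticks(y)
    ax.set_yticklabels([r.endpoint for r in ordered])
    ax.set_xlabel("MCDA score difference at weight mean ± 2 SD")
    return ax


def density_plot(draws: np.ndarray, axes=None):
    """PDF and CDF of the simulated score difference; CDF(0) is P(net benefit)."""
    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(10, 4))
    tab = density_outputs(draws)
    axes[0].plot(tab["x"], tab["pdf"], color="steelblue")
    axes[0].axvline(0, color="grey", lw=0.8)
    axes[0].set_xlabel("MCDA score difference")
    axes[0].set_ylabel("density")
    axes[1].plot(tab["x"], tab["cdf"], color="steelblue")
    axes[1].axvline(0, color="grey", lw=0.8)
    axes[1].set_xlabel("MCDA score difference")
    axes[1].set_ylabel("cumulative probability")
    return axes


def temporal_plot(temporal: TemporalBR, ax: plt.Axes | None = None) -> plt.Axes:
    """Benefit-risk trajectory with 95% band; negative favours the active arm."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    ax.plot(temporal.grid_days, temporal.delta_s, color="black")
    ax.fill_between(temporal.grid_days, temporal.ci_lo, temporal.ci_hi,
                    color="steelblue", alpha=0.3)
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xlabel("days since randomization")
    ax.set_ylabel(temporal.units)
    return ax
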