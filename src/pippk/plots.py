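"""Diagnostic plots (matplotlib figures; callers decide where to save)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .diagnostics import BlandAltman, VpcResult
from .posterior import PredictionRecord


def obs_vs_pred(records: list[PredictionRecord], which: str = "population"):
    """Observed vs predicted scatter with the identity line."""
    key = "population_predicted" if which == "population" else "individual_predicted"
    pred = [getattr(r, key) for r in records]
    obs = [r.observed for r in records]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(pred, obs, s=18, alpha=0.7, edgecolor="none")
    lim = [0, max(max(pred), max(obs)) * 1.05]
    ax.plot(lim, lim, "k--", lw=1)
    ax.set_xlabel(f"{which} predicted (mg/L)")
    ax.set_ylabel("observed (mg/L)")
    ax.set_xlim(lim)
    ax.set_ylim(lim)
    fig.tight_layout()
    return fig


def vpc_plot(result: VpcResult):
    """Visual predictive check: simulated 5th-95th band vs observations."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(result.bin_times, result.q05, result.q95, alpha=0.3, label="5th-95th")
    ax.plot(result.bin_times, result.q50, lw=1.5, label="median")
    ax.scatter(result.observed_times, result.observed, s=14, c="k", zorder=3, label="observed")
    ax.set_xlabel("time after dose (h)")
    ax.set_ylabel("concentration (mg/L)")
    ax.legend(frameon=False)
    ax.set_title(f"coverage {result.coverage:.2f}")
    fig.tight_layout()
    return fig


def bland_altman_plot(result: BlandAltman):
    """Differences vs index with bias and limits of agreement."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(np.arange(result.differences.size), result.differences, s=14)
    for y, style in ((result.bias, "-"), (result.lower_loa, "--"), (result.upper_loa, "--")):
        ax.axhline(y, color="k", ls=style, lw=1)
    unit = "%" if result.scale == "percent_of_mean" else "mg/L"
    ax.set_ylabel(f"observed - predicted ({unit})")
    ax.set_xlabel("pair")
    fig.tight_layout()
    return fig
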