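"""Comparison figures: occupancy, survival fits and cumulative incidence."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .curves import OccupancyTrace, SurvivalCurve
from .estimation import KMEstimate


def plot_progression_occupancy(
    traces: dict[str, OccupancyTrace],
    band: dict | None = None,
    ax=None,
    title: str = "Probability of being in progression",
):
    """Progression-state occupancy per approach, with an optional bootstrap band."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for label, trace in traces.items():
        ax.plot(trace.times, trace.prog, label=label)
    if band is not None:
        ax.fill_between(band["grid"], band["low"], band["high"], alpha=0.25,
                        color="grey", label="observed 95% bootstrap band")
        ax.plot(band["grid"], band["point"], color="black", lw=1, ls="--",
                label="observed proportion")
    ax.set_xlabel("years since randomisation")
    ax.set_ylabel("P(in progression)")
    ax.set_title(title)
    ax.legend()
    return ax


def plot_survival(
    curves: dict[str, SurvivalCurve],
    km: KMEstimate | None = None,
    ax=None,
    ylabel: str = "survival probability",
    title: str = "",
):
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    if km is not None:
        grid = np.linspace(0, km.times.max(), 400)
        ax.step(grid, km.evaluate(grid), where="post", color="black", lw=1,
                label="Kaplan-Meier")
    for label, c in curves.items():
        ax.plot(c.times, c.survival, label=label)
    ax.set_xlabel("years since randomisation")
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    ax.legend()
    return ax


def plot_cumulative_incidence(
    incidence: dict[int, KMEstimate],
    model_curves: dict[str, SurvivalCurve] | None = None,
    ax=None,
    title: str = "Cumulative incidence",
):
    """Nonparametric cumulative incidence curves (and model predictions)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    from .estimation import evaluate_incidence

    for cause, est in incidence.items():
        grid = np.linspace(0, est.times.max(), 400)
        ax.step(grid, evaluate_incidence(est, grid), where="post",
                label=f"cause {cause} (observed)")
    if model_curves:
        for label, c in model_curves.items():
            ax.plot(c.times, c.survival, ls="--", label=label)
    ax.set_xlabel("years since randomisation")
    ax.set_ylabel("cumulative incidence")
    ax.set_title(title)
    ax.legend()
    return ax
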