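"""Shared time-grid containers: survival curves and state-occupancy traces.

Times are always in years. The standard reporting grid is 1/12-year
increments on [0, horizon], matching a monthly model cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: States of the illness-death model.
PF, PROG, DEAD = 1, 2, 3

STATE_NAMES = {PF: "pf", PROG: "prog", DEAD: "dead"}


def reporting_grid(horizon: float = 15.0, step: float = 1.0 / 12.0) -> np.ndarray:
    """Uniform evaluation grid 0, step, 2*step, ..., horizon."""
    n = int(round(horizon / step))
    return np.arange(n + 1) * step


@dataclass
class SurvivalCurve:
    """A survival function evaluated on a time grid.

    Attributes
    ----------
    times : array of evaluation times (years), non-decreasing, times[0] == 0.
    survival : array of probabilities, survival[0] == 1, non-increasing for
        model-based curves (step functions from estimators are also allowed).
    label : optional free-text description.
    """

    times: np.ndarray
    survival: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times.shape != self.survival.shape:
            raise ValueError("times and survival must have matching shapes")
        if self.times.size and self.times[0] != 0.0:
            raise ValueError("survival curves must start at t=0")

    def __call__(self, t):
        """Linear interpolation between grid points."""
        return np.interp(t, self.times, self.survival)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival})


@dataclass
class OccupancyTrace:
    """Per-state occupancy probabilities of the three-state model on a grid.

    ``mc_se`` holds per-state Monte-Carlo standard errors when the trace was
    produced by path simulation; it is None for deterministic traces.
    """

    times: np.ndarray
    pf: np.ndarray
    prog: np.ndarray
    dead: np.ndarray
    mc_se: dict[str, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pf = np.asarray(self.pf, dtype=float)
        self.prog = np.asarray(self.prog, dtype=float)
        self.dead = np.asarray(self.dead, dtype=float)
        for a in (self.pf, self.prog, self.dead):
            if a.shape != self.times.shape:
                raise ValueError("state arrays must match the time grid")

    @property
    def alive(self) -> np.ndarray:
        return self.pf + self.prog

    def validate(self, atol: float = 1e-12) -> None:
        """Check conservation and monotone death occupancy.

        For simulated traces the conservation check is exact by construction;
        ``atol`` applies to deterministic traces.
        """
        total = self.pf + self.prog + self.dead
        if np.max(np.abs(total - 1.0)) > atol:
            raise ValueError("state occupancies do not sum to 1")
        if np.any(np.diff(self.dead) < -atol):
            raise ValueError("death occupancy must be non-decreasing")

    def to_frame(self, arm: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"time": self.times, "pf": self.pf, "prog": self.prog, "dead": self.dead}
        )
        if arm is not None:
            df.insert(1, "arm", arm)
        return df


def occupancy_from_curves(
    times: np.ndarray, os_surv: np.ndarray, pfs_surv: np.ndarray
) -> tuple[OccupancyTrace, bool]:
    """Partition overall survival with progression-free survival.

    PF = PFS, Prog = max(OS - PFS, 0), Dead = 1 - OS.  Returns the trace and
    a flag indicating whether the OS < PFS flooring was ever active (the two
    curves are fitted independently, so crossing is possible).
    """
    diff = np.asarray(os_surv) - np.asarray(pfs_surv)
    floored = bool(np.any(diff < 0))
    prog = np.maximum(diff, 0.0)
    pf = np.asarray(pfs_surv, dtype=float)
    dead = 1.0 - pf - prog
    return OccupancyTrace(times=times, pf=pf, prog=prog, dead=dead), floored
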