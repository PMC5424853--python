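"""Discounted Life-Year / QALY integration and incremental ratios.

Areas under occupancy curves are taken by the trapezoidal rule on a uniform
1/12-year grid; the discount factor (1+r)^(−t) is applied pointwise before
integration (continuous compounding of the annual rate).  QALYs weight
state time by a constant per-state utility.  Incrementals are treated −
control; ICER = Δcost / Δeffect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .curves import OccupancyTrace


@dataclass
class EconomicConfig:
    """Valuation settings.

    discount_rate: annual rate (0.035 = 3.5%/year).
    u_pf / u_prog: utilities of the progression-free / progression states.
    costs: optional per-arm total discounted cost (currency units).
    """

    discount_rate: float = 0.035
    u_pf: float = 0.8
    u_prog: float = 0.6
    horizon: float = 15.0
    step: float = 1.0 / 12.0
    costs: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.u_prog <= 1.0 and 0.0 <= self.u_pf <= 1.0):
            raise ValueError("utilities must lie in [0, 1]")
        if self.discount_rate < 0 or self.horizon <= 0:
            raise ValueError("need discount_rate >= 0 and horizon > 0")


def _check_uniform(times: np.ndarray, step: float | None = None) -> float:
    d = np.diff(times)
    if d.size == 0:
        raise ValueError("grid must contain at least two points")
    if np.max(np.abs(d - d[0])) > 1e-9:
        raise ValueError("grid must be uniform")
    if step is not None and abs(d[0] - step) > 1e-9:
        raise ValueError(f"grid step {d[0]} differs from required {step}")
    return float(d[0])


def discounted_area(
    times: np.ndarray,
    values: np.ndarray,
    rate: float = 0.035,
    method: str = "trapezoid",
) -> float:
    """Trapezoid integral of v(t)·(1+r)^(−t) over the uniform grid (years)."""
    if method != "trapezoid":
        raise ValueError("only the trapezoidal rule is supported")
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    _check_uniform(times)
    disc = (1.0 + rate) ** (-times)
    return float(np.trapezoid(values * disc, times))


def period_split(
    times: np.ndarray,
    values: np.ndarray,
    boundary: float,
    rate: float = 0.035,
) -> dict[str, float]:
    """Split the discounted area at a boundary into observed + extrapolated.

    The split is additive to machine precision: observed + extrapolated
    equals the whole-horizon area.  An off-grid boundary is snapped to the
    nearest grid point with a warning.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    _check_uniform(times)
    idx = int(np.argmin(np.abs(times - boundary)))
    if abs(times[idx] - boundary) > 1e-9:
        import warnings

        warnings.warn(
            f"boundary {boundary} snapped to grid point {times[idx]:.6f}",
            stacklevel=2,
        )
    disc = (1.0 + rate) ** (-times)
    v = values * disc
    observed = float(np.trapezoid(v[: idx + 1], times[: idx + 1])) if idx > 0 else 0.0
    extrapolated = float(np.trapezoid(v[idx:], times[idx:])) if idx < times.size - 1 else 0.0
    return {"observed": observed, "extrapolated": extrapolated, "boundary": float(times[idx])}


@dataclass
class ArmSummary:
    ly_pf: float
    ly_prog: float
    total_cost: float | None = None

    @property
    def ly_total(self) -> float:
        return self.ly_pf + self.ly_prog

    def qaly(self, u_pf: float, u_prog: float) -> float:
        return u_pf * self.ly_pf + u_prog * self.ly_prog


@dataclass
class EconomicSummary:
    """Per-arm discounted LY/QALY with incrementals and ICERs.

    ``arms`` maps arm name -> ArmSummary; ``treated``/``control`` name the
    comparison direction (incremental = treated − control).
    """

    arms: dict[str, ArmSummary]
    config: EconomicConfig
    treated: str
    control: str
    notes: dict = field(default_factory=dict)

    def _inc(self, attr_fn) -> float:
        return attr_fn(self.arms[self.treated]) - attr_fn(self.arms[self.control])

    @property
    def incremental_ly(self) -> float:
        return self._inc(lambda a: a.ly_total)

    @property
    def incremental_ly_pf(self) -> float:
        return self._inc(lambda a: a.ly_pf)

    @property
    def incremental_ly_prog(self) -> float:
        return self._inc(lambda a: a.ly_prog)

    @property
    def incremental_qaly(self) -> float:
        u = self.config
        return self._inc(lambda a: a.qaly(u.u_pf, u.u_prog))

    @property
    def incremental_cost(self) -> float | None:
        a, b = self.arms[self.treated], self.arms[self.control]
        if a.total_cost is None or b.total_cost is None:
            return None
        return a.total_cost - b.total_cost

    def icer(self, effect: str = "qaly") -> float | None:
        """Δcost / Δeffect; None when costs are absent, NaN when Δeffect=0."""
        dc = self.incremental_cost
        if dc is None:
            return None
        de = self.incremental_qaly if effect == "qaly" else self.incremental_ly
        if de == 0.0:
            return float("nan")
        return dc / de

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per arm plus an incremental row."""
        u = self.config
        rows = []
        for name, a in self.arms.items():
            rows.append(
                {
                    "arm": name,
                    "ly_total": a.ly_total,
                    "ly_pf": a.ly_pf,
                    "ly_prog": a.ly_prog,
                    "qaly_total": a.qaly(u.u_pf, u.u_prog),
                    "qaly_pf": u.u_pf * a.ly_pf,
                    "qaly_prog": u.u_prog * a.ly_prog,
                    "total_cost": a.total_cost,
                }
            )
        rows.append(
            {
                "arm": "incremental",
                "ly_total": self.incremental_ly,
                "ly_pf": self.incremental_ly_pf,
                "ly_prog": self.incremental_ly_prog,
                "qaly_total": self.incremental_qaly,
                "qaly_pf": u.u_pf * self.incremental_ly_pf,
                "qaly_prog": u.u_prog * self.incremental_ly_prog,
                "total_cost": self.incremental_cost,
            }
        )
        return pd.DataFrame(rows)


def summarize(
    traces: Mapping[str, OccupancyTrace],
    config: EconomicConfig,
    treated: str = "rfc",
    control: str = "fc",
) -> EconomicSummary:
    """Discounted per-state areas, QALY weighting and incremental ratios."""
    arms = {}
    for name, trace in traces.items():
        ly_pf = discounted_area(trace.times, trace.pf, config.discount_rate)
        ly_prog = discounted_area(trace.times, trace.prog, config.discount_rate)
        cost = config.costs.get(name) if config.costs else None
        arms[name] = ArmSummary(ly_pf=ly_pf, ly_prog=ly_prog, total_cost=cost)
    return EconomicSummary(arms=arms, config=config, treated=treated, control=control)
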