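"""Discrete-time (monthly) three-state cohort model.

Implements the manufacturer-style transition rules: a constant monthly
progression→death probability (derived from the inverse of the restricted
KM mean of post-progression survival), a per-arm observed monthly
progression-free→death probability taken as the maximum with an optional
age-specific background mortality, and a progression-free stay probability
equal to the monthly conditional survival of a Weibull PFS regression.
Because the progression→death probability is constant, the discrete model
is memoryless in the progression state and "clock-reset" vs "clock-forward"
bookkeeping give identical traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .curves import OccupancyTrace
from .hazard_models import ParametricHazardModel

_ARM_COVARIATE = {"fc": 0.0, "rfc": 1.0}


@dataclass
class TransitionRules:
    """Inputs of the monthly cohort model.

    ``p_pf_death_monthly`` maps arm name to the observed monthly probability
    of death while progression-free.  ``life_table`` (columns: age,
    annual_mortality_probability) switches on the max-with-background rule;
    it is off by default so results do not depend on an unpublished table.
    """

    pfs_model: ParametricHazardModel
    p_prog_death: float = 0.0405
    p_pf_death_monthly: Mapping[str, float] = field(
        default_factory=lambda: {"rfc": 0.0012, "fc": 0.00139}
    )
    life_table: pd.DataFrame | None = None
    cohort_start_age: float = 61.0

    def __post_init__(self) -> None:
        probs = [self.p_prog_death, *self.p_pf_death_monthly.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("transition probabilities must lie in [0, 1]")


@dataclass
class CohortTrace:
    """Occupancy per cycle; time of cycle k is k/cycles_per_year years."""

    cycles: np.ndarray
    pf: np.ndarray
    prog: np.ndarray
    dead: np.ndarray
    cycles_per_year: int = 12

    @property
    def times(self) -> np.ndarray:
        return self.cycles / float(self.cycles_per_year)

    def as_occupancy(self) -> OccupancyTrace:
        return OccupancyTrace(self.times, self.pf, self.prog, self.dead)


def stay_probability(
    pfs_model: ParametricHazardModel,
    k: int,
    covariates=None,
    cycles_per_year: int = 12,
) -> float:
    """Conditional per-cycle survival S((k+1)Δ) / S(kΔ) of the PFS model."""
    s0 = float(pfs_model.survival(k / cycles_per_year, covariates))
    if s0 == 0.0:
        return 0.0
    return float(pfs_model.survival((k + 1) / cycles_per_year, covariates)) / s0


def annual_to_monthly(q: float) -> float:
    """Compound conversion 1 − (1 − q)^(1/12) of an annual probability."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("annual probability must lie in [0, 1]")
    return float(1.0 - (1.0 - q) ** (1.0 / 12.0))


def background_monthly(life_table: pd.DataFrame, age: float) -> float:
    """Monthly background mortality at the given age (last row carried)."""
    ages = life_table["age"].to_numpy(dtype=float)
    q = life_table["annual_mortality_probability"].to_numpy(dtype=float)
    if age > ages[-1]:
        warnings.warn(
            f"age {age:.1f} beyond life table; last row carried forward",
            stacklevel=2,
        )
        return annual_to_monthly(q[-1])
    idx = int(np.searchsorted(ages, age, side="right") - 1)
    return annual_to_monthly(q[max(idx, 0)])


def pf_death_probability(
    rules: TransitionRules, k: int, arm: str, cycles_per_year: int = 12
) -> float:
    """max(observed monthly probability, background monthly probability)."""
    observed = float(rules.p_pf_death_monthly[arm])
    if rules.life_table is None:
        return observed
    age = rules.cohort_start_age + k / cycles_per_year
    return max(observed, background_monthly(rules.life_table, age))


def run_cohort(
    rules: TransitionRules,
    arm: str,
    horizon: float = 15.0,
    cycles_per_year: int = 12,
) -> CohortTrace:
    """Propagate the cohort over discrete cycles (monthly by default).

    pf(k+1) = pf(k)·stay(k);
    progression inflow = pf(k)·(1 − stay(k) − p_pf_death(k));
    prog(k+1) = prog(k)·(1 − p_prog_death) + inflow; dead absorbs the rest.
    Conservation is exact by construction.  With a non-monthly
    ``cycles_per_year`` the rules' probabilities are interpreted per cycle
    (the caller must supply them on that cycle length).
    """
    n = int(round(horizon * cycles_per_year))
    cov = {"treatment": _ARM_COVARIATE.get(arm, 0.0)} if rules.pfs_model.coefficients else None
    pf = np.empty(n + 1)
    prog = np.empty(n + 1)
    dead = np.empty(n + 1)
    pf[0], prog[0], dead[0] = 1.0, 0.0, 0.0
    for k in range(n):
        stay = stay_probability(rules.pfs_model, k, cov, cycles_per_year)
        p_pfd = pf_death_probability(rules, k, arm, cycles_per_year)
        p_to_prog = 1.0 - stay - p_pfd
        if p_to_prog < 0:
            raise ValueError(
                f"cycle {k}: stay + pf-death probabilities exceed 1 "
                f"(stay={stay:.6f}, p_pf_death={p_pfd:.6f})"
            )
        pf[k + 1] = pf[k] * stay
        prog[k + 1] = prog[k] * (1.0 - rules.p_prog_death) + pf[k] * p_to_prog
        dead[k + 1] = dead[k] + prog[k] * rules.p_prog_death + pf[k] * p_pfd
    return CohortTrace(np.arange(n + 1), pf, prog, dead, cycles_per_year)


def read_life_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"age", "annual_mortality_probability"}
    if not need <= set(df.columns):
        raise ValueError(f"life table must have columns {sorted(need)}")
    return df.sort_values("age").reset_index(drop=True)


def rules_from_fixture(raw: dict, life_table: pd.DataFrame | None = None) -> TransitionRules:
    """Build TransitionRules from the bundled fixture dict."""
    return TransitionRules(
        pfs_model=raw["pfs_model"],
        p_prog_death=float(raw["p_prog_death_monthly"]),
        p_pf_death_monthly={k: float(v) for k, v in raw["p_pf_death_monthly"].items()},
        life_table=life_table,
        cohort_start_age=float(raw.get("cohort_start_age", 61.0)),
    )
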