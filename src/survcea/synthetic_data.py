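"""Synthetic two-arm trial generator from the illness-death model.

Emulates the case-study trial design — 408 treated (RFC) and 409 control
(FC) patients, uniform accrual over one year, administrative cutoff four
years after trial start (so individual follow-up is 3-4 years) — with
event times drawn from the semi-Markov Gompertz model by inverse
cumulative-hazard sampling.  The generator exists so that every fitting
stage (KM, tail selection, parametric MLE, recovery loops) is testable
without the original patient data; all times are on the subject's own
study-entry clock, in years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hazard_models import ParametricHazardModel
from .multistate_semimarkov import T12, T13, T23, MultiStateSpec, apply_treatment


@dataclass
class TrialDesign:
    """Two-arm trial design around a generating multi-state model.

    ``spec`` is the control-arm model; ``treatment_hrs`` scales the treated
    arm's transition hazards.  ``dropout_rate`` adds optional exponential
    loss to follow-up on top of administrative censoring (off by default).
    """

    spec: MultiStateSpec
    treatment_hrs: dict = field(default_factory=dict)
    n_treated: int = 408
    n_control: int = 409
    accrual_years: float = 1.0
    cutoff_years: float = 4.0
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.cutoff_years <= 0 or min(self.n_treated, self.n_control) < 1:
            raise ValueError("need cutoff > 0 and at least one subject per arm")


def _sample_arm(
    spec: MultiStateSpec, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Latent progression and death times (study-entry clock), inf if never."""
    t12 = spec.Hinv(T12, rng.exponential(size=n))
    t13 = spec.Hinv(T13, rng.exponential(size=n))
    progressed = t12 < t13
    t_prog = np.where(progressed, t12, np.inf)
    e23 = rng.exponential(size=n)
    if spec.clocks[T23] == "reset":
        death_after = t_prog + spec.Hinv(T23, e23)
    else:
        base = spec.H(T23, np.where(np.isfinite(t_prog), t_prog, 0.0))
        death_after = spec.Hinv(T23, base + e23)
    t_death = np.where(progressed, death_after, t13)
    return t_prog, t_death


def simulate_trial(design: TrialDesign, seed: int) -> pd.DataFrame:
    """Wide-format IPD: id, arm, time_prog, time_death, time_censor.

    Censoring is administrative — cutoff minus the subject's accrual time —
    optionally tightened by exponential dropout.  Progression is recorded
    only if it precedes censoring; a death after censoring is censored, and
    event indicators are consistent by construction (an observed death after
    progression implies the progression itself was observed).
    """
    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for arm_code, n in ((1, design.n_treated), (0, design.n_control)):
        spec = (
            apply_treatment(design.spec, design.treatment_hrs)
            if arm_code == 1 and design.treatment_hrs
            else design.spec
        )
        t_prog, t_death = _sample_arm(spec, n, rng)
        entry = rng.uniform(0.0, design.accrual_years, size=n)
        censor = design.cutoff_years - entry
        if design.dropout_rate > 0:
            censor = np.minimum(censor, rng.exponential(1.0 / design.dropout_rate, n))
        obs_prog = np.where(t_prog <= censor, t_prog, np.nan)
        obs_death = np.where(t_death <= censor, t_death, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "id": offset + np.arange(n),
                    "arm": arm_code,
                    "time_prog": obs_prog,
                    "time_death": obs_death,
                    "time_censor": censor,
                }
            )
        )
        offset += n
    return pd.concat(frames, ignore_index=True)


def km_fixture(
    model: ParametricHazardModel,
    n: int,
    seed: int,
    censor_time: float | None = None,
) -> pd.DataFrame:
    """iid single-event sample from a parametric survival model.

    Draws by inverse cumulative hazard at unit-exponential deviates, with
    optional administrative censoring; the KM of the output converges to
    the model's survival function.  Columns: time, status.
    """
    rng = np.random.default_rng(seed)
    t = model.inverse_cumulative_hazard(rng.exponential(size=n), allow_inf=True)
    if censor_time is None:
        status = np.isfinite(t).astype(int)
        cap = np.nanmax(np.where(np.isfinite(t), t, np.nan)) * 2 + 1.0
        time = np.where(np.isfinite(t), t, cap)
    else:
        status = (t <= censor_time).astype(int)
        time = np.minimum(t, censor_time)
    return pd.DataFrame({"time": time, "status": status})


def life_table_fixture(
    start_age: int = 30,
    end_age: int = 100,
    base_rate: float = 5e-5,
    slope: float = 0.095,
) -> pd.DataFrame:
    """Synthetic life table following a Gompertz mortality law.

    Annual mortality probability q(age) = 1 − exp(−base_rate·e^(slope·age));
    defaults give q ≈ 0.0008 at age 30 rising steeply in old age, a
    realistic adult-mortality shape for exercising the max-with-background
    rule.  This is a synthetic stand-in, not any national table.
    """
    ages = np.arange(start_age, end_age + 1)
    q = 1.0 - np.exp(-base_rate * np.exp(slope * ages))
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("parameters give probabilities outside (0, 1)")
    return pd.DataFrame({"age": ages, "annual_mortality_probability": q})
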