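"""Tail extrapolation of Kaplan-Meier curves by linearized regression.

When heavy censoring makes a whole-curve parametric fit implausible (the
extrapolation never approaches zero by the horizon), the curve tail is
fitted instead: the survival function is rearranged into a form linear in
(a transform of) time, ordinary least squares is run on the KM step points
at or after a chosen tail start, and the fit is back-transformed:

* exponential: log S = −λ·t, regression through the origin;
* Weibull:     log(−log S) = a + b·log t with a = log λ, b = shape.

The tail start is chosen as the latest candidate event time whose fitted
tail reaches (approximately) zero by the horizon.  A comparator arm without
an adequate tail of its own can be extrapolated by mapping the reference
tail through the observed-period hazard ratio, S_new = S_ref^hr.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .curves import SurvivalCurve
from .estimation import KMEstimate
from .hazard_models import ParametricHazardModel


@dataclass
class TailFit:
    """Back-transformed linear-regression fit to a KM tail.

    For family "weibull" the coefficients are (a, b) of
    log(−log S) = a + b·log t, so S(t) = exp(−e^a · t^b); for family
    "exponential" the single coefficient is the rate λ of S(t) = e^(−λt)
    (zero intercept imposed).
    """

    family: str
    tail_start: float
    coefficients: dict[str, float]
    source_times: np.ndarray = field(default=None, repr=False)
    source_survival: np.ndarray = field(default=None, repr=False)

    def survival(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.family == "exponential":
            return np.exp(-self.coefficients["rate"] * t)
        a, b = self.coefficients["a"], self.coefficients["b"]
        with np.errstate(divide="ignore"):
            out = np.exp(-np.exp(a) * np.where(t > 0, t, 0.0) ** b)
        return np.where(t > 0, out, 1.0)

    def as_model(self) -> ParametricHazardModel:
        if self.family == "exponential":
            return ParametricHazardModel(
                "exponential", {"log_scale": -np.log(self.coefficients["rate"])}
            )
        return ParametricHazardModel(
            "weibull_tail",
            {"log_rate": self.coefficients["a"], "shape": self.coefficients["b"]},
        )


def fit_tail(km: KMEstimate, tail_start: float, family: str = "weibull") -> TailFit:
    """OLS on the transformed KM step points at or after ``tail_start``.

    One point per distinct event time, unweighted; points with S = 0 or
    S = 1 (transform undefined) are dropped with a warning.
    """
    if family not in ("exponential", "weibull"):
        raise ValueError("tail family must be 'exponential' or 'weibull'")
    sel = km.times >= tail_start
    t = km.times[sel]
    s = km.survival[sel]
    usable = (s > 0.0) & (s < 1.0)
    if np.any(~usable):
        warnings.warn(
            "dropping tail points with S=0 or S=1 (transform undefined)",
            stacklevel=2,
        )
    t, s = t[usable], s[usable]
    if t.size < 2:
        raise ValueError("need at least 2 usable KM points in the tail")
    if family == "exponential":
        # log S = -lambda * t, intercept constrained to zero
        y = np.log(s)
        slope = float(np.sum(t * y) / np.sum(t * t))
        coef = {"rate": -slope}
    else:
        x = np.log(t)
        y = np.log(-np.log(s))
        b, a = np.polyfit(x, y, 1)
        coef = {"a": float(a), "b": float(b)}
    return TailFit(family, float(tail_start), coef, t.copy(), s.copy())


def select_tail_start(
    km: KMEstimate,
    family: str = "weibull",
    horizon: float = 15.0,
    zero_tol: float = 0.005,
) -> float | None:
    """Latest event time whose fitted tail reaches ~zero by the horizon.

    Candidates are the unique observed event times; a candidate qualifies
    when the back-transformed extrapolation has S(horizon) <= zero_tol (no
    Weibull is exactly zero at finite time, hence the tolerance).  Returns
    None when no candidate qualifies.
    """
    best = None
    for start in km.times:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_tail(km, start, family)
        except ValueError:
            continue
        if fit.family == "weibull" and fit.coefficients["b"] <= 0:
            continue  # non-decreasing-to-zero extrapolation
        if fit.survival(horizon) <= zero_tol and (best is None or start > best):
            best = float(start)
    return best


def map_by_hazard_ratio(reference: SurvivalCurve, hr: float) -> SurvivalCurve:
    """Proportional-hazards mapping S_new(t) = S_ref(t)^hr pointwise."""
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    return SurvivalCurve(
        times=reference.times,
        survival=reference.survival**hr,
        label=f"{reference.label} ^ hr={hr}".strip(),
    )


def stitch(
    observed_survival,
    tail,
    junction: float,
    times: np.ndarray,
    tail_time_mode: str = "absolute",
    renormalize: bool = False,
) -> tuple[SurvivalCurve, float]:
    """Piecewise curve: observed model to the junction, tail curve beyond.

    ``observed_survival`` and ``tail`` are callables t → S(t) (a TailFit, a
    fitted model's ``survival`` or any function).  In the default
    "absolute" mode the tail is evaluated at absolute study time; in
    "from-tail-start" mode at time since the junction.  Returns the stitched
    curve and the junction discontinuity |S_obs(j) − S_tail(j)|, which is
    reported, not repaired, unless ``renormalize`` is set (conditional
    survival multiplication S_obs(j)·S_tail(t)/S_tail(j)).
    """
    if tail_time_mode not in ("absolute", "from-tail-start"):
        raise ValueError("tail_time_mode must be 'absolute' or 'from-tail-start'")
    times = np.asarray(times, dtype=float)
    tail_fn = tail.survival if hasattr(tail, "survival") else tail
    obs = np.asarray(observed_survival(times), dtype=float)
    if tail_time_mode == "absolute":
        tl = np.asarray(tail_fn(times), dtype=float)
        tail_at_junction = float(tail_fn(np.asarray(junction)))
    else:
        shifted = np.maximum(times - junction, 0.0)
        tl = np.asarray(tail_fn(shifted), dtype=float)
        tail_at_junction = 1.0
    obs_at_junction = float(observed_survival(np.asarray(junction)))
    gap = abs(obs_at_junction - tail_at_junction)
    if renormalize and tail_at_junction > 0:
        tl = obs_at_junction * tl / tail_at_junction
    surv = np.where(times <= junction, obs, tl)
    return SurvivalCurve(times=times, survival=surv), gap
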