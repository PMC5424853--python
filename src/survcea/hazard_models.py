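"""Parametric hazard families for transition and outcome modelling.

Six families are supported — exponential, Weibull, Gompertz, log-logistic,
log-normal and generalized gamma — plus the tail reparametrization of the
Weibull used when a curve tail is fitted by linearized regression.

Parameter conventions (time in years throughout):

``exponential``
    ``{"log_scale": c}`` with hazard rate λ = exp(−c), so H(t) = exp(−c)·t.
``weibull``
    ``{"log_scale": s, "log_shape": k}`` with
    S(t) = exp(−(t/e^s)^(e^k)) — the proportional-hazards fitted form.
``weibull_tail``
    ``{"log_rate": a, "shape": b}`` with S(t) = exp(−e^a · t^b), i.e. the
    intercept/slope of the linearization log(−log S) = a + b·log t.
``gompertz``
    ``{"shape": g, "log_scale": c}`` with hazard h(t) = exp(c)·exp(g·t) and
    H(t) = exp(c)/g · (exp(g·t) − 1) for g ≠ 0.  The name "scale" is the log
    baseline rate.  For g < 0 the total hazard is bounded by exp(c)/|g| and a
    fraction of subjects never experience the event.
``loglogistic`` / ``lognormal``
    standard AFT location-scale: ``{"mu": μ, "sigma": σ}`` on log time.
``gengamma``
    ``{"mu": μ, "sigma": σ, "q": Q}`` (three-parameter generalized gamma);
    Q = 1 reduces to the Weibull, Q → 0 to the log-normal.

Covariates act multiplicatively on the hazard for PH families
(``effect_type="ph"``: H(t|x) = exp(Σβx)·H0(t)) and as a location shift of μ
for AFT families (``effect_type="aft"``: μ|x = μ + Σβx).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import special, stats

FAMILIES = (
    "exponential",
    "weibull",
    "weibull_tail",
    "gompertz",
    "loglogistic",
    "lognormal",
    "gengamma",
)

#: Families whose covariate effects are proportional hazards by default.
PH_FAMILIES = ("exponential", "weibull", "weibull_tail", "gompertz")
#: Families fitted on the accelerated-failure-time scale.
AFT_FAMILIES = ("loglogistic", "lognormal", "gengamma")

_PARAM_KEYS = {
    "exponential": ("log_scale",),
    "weibull": ("log_scale", "log_shape"),
    "weibull_tail": ("log_rate", "shape"),
    "gompertz": ("shape", "log_scale"),
    "loglogistic": ("mu", "sigma"),
    "lognormal": ("mu", "sigma"),
    "gengamma": ("mu", "sigma", "q"),
}

_GOMPERTZ_LINEAR_TOL = 1e-12


class EventNeverError(ValueError):
    """Requested cumulative hazard exceeds the total hazard H(∞).

    Raised by :func:`inverse_cumulative_hazard` for bounded-hazard families
    (Gompertz with negative shape) when the event never occurs.  Sampling
    code catches this / uses the vectorized path that returns ``inf``.
    """


@dataclass
class ParametricHazardModel:
    """One transition's (or outcome's) parametric hazard model.

    Parameters are the family-specific baseline parameters; ``coefficients``
    maps covariate names to log hazard ratios (PH families) or AFT location
    effects (AFT families).
    """

    family: str
    params: dict[str, float]
    coefficients: dict[str, float] = field(default_factory=dict)
    standard_errors: dict[str, float] | None = None
    effect_type: str | None = None  # "ph" | "aft"; default inferred from family
    loglik: float | None = None
    param_standard_errors: dict[str, float] | None = None
    n_events: int | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        missing = [k for k in _PARAM_KEYS[self.family] if k not in self.params]
        if missing:
            raise ValueError(f"{self.family} model missing parameters {missing}")
        if self.effect_type is None:
            self.effect_type = "ph" if self.family in PH_FAMILIES else "aft"
        if self.effect_type not in ("ph", "aft"):
            raise ValueError("effect_type must be 'ph' or 'aft'")
        for key in ("sigma",):
            if key in self.params and self.params[key] <= 0:
                raise ValueError(f"{key} must be positive")

    # -- covariate handling -------------------------------------------------
    def linear_predictor(self, covariates: Mapping[str, float] | None) -> float:
        covariates = covariates or {}
        eta = 0.0
        for name, beta in self.coefficients.items():
            if name not in covariates:
                raise ValueError(f"missing covariate {name!r}")
            eta += beta * float(covariates[name])
        return eta

    def n_params(self) -> int:
        return len(_PARAM_KEYS[self.family]) + len(self.coefficients)

    # -- public surface -----------------------------------------------------
    def survival(self, t, covariates: Mapping[str, float] | None = None):
        return survival(self, t, covariates)

    def hazard(self, t, covariates: Mapping[str, float] | None = None):
        return hazard(self, t, covariates)

    def cumulative_hazard(self, t, covariates: Mapping[str, float] | None = None):
        return cumulative_hazard(self, t, covariates)

    def inverse_cumulative_hazard(self, H, covariates=None, allow_inf: bool = False):
        return inverse_cumulative_hazard(self, H, covariates, allow_inf=allow_inf)


# ---------------------------------------------------------------------------
# Baseline closed forms
# ---------------------------------------------------------------------------


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return t


def _gengamma_H0(mu: float, sigma: float, q: float, t: np.ndarray) -> np.ndarray:
    # Q→0 limit is the log-normal; treat |Q| below tol as the limit.
    with np.errstate(divide="ignore"):
        w = (np.log(t) - mu) / sigma
    if abs(q) < 1e-8:
        sf = stats.norm.sf(w)
    else:
        qq = q**-2
        gx = qq * np.exp(q * w)
        sf = special.gammaincc(qq, gx) if q > 0 else special.gammainc(qq, gx)
    sf = np.clip(sf, 1e-300, 1.0)
    return -np.log(sf)


def _H0(family: str, p: Mapping[str, float], t: np.ndarray) -> np.ndarray:
    if family == "exponential":
        return np.exp(-p["log_scale"]) * t
    if family == "weibull":
        return (t / np.exp(p["log_scale"])) ** np.exp(p["log_shape"])
    if family == "weibull_tail":
        return np.exp(p["log_rate"]) * t ** p["shape"]
    if family == "gompertz":
        g, c = p["shape"], p["log_scale"]
        if abs(g) < _GOMPERTZ_LINEAR_TOL:
            return np.exp(c) * t
        return np.exp(c) / g * np.expm1(g * t)
    if family == "loglogistic":
        z = t * np.exp(-p["mu"])
        with np.errstate(divide="ignore"):
            return np.log1p(z ** (1.0 / p["sigma"]))
    if family == "lognormal":
        with np.errstate(divide="ignore"):
            w = (np.log(t) - p["mu"]) / p["sigma"]
        return -stats.norm.logsf(w)
    if family == "gengamma":
        return _gengamma_H0(p["mu"], p["sigma"], p["q"], t)
    raise ValueError(f"unknown family {family!r}")


def _h0(family: str, p: Mapping[str, float], t: np.ndarray) -> np.ndarray:
    if family == "exponential":
        return np.full_like(t, np.exp(-p["log_scale"]))
    if family == "weibull":
        scale, shape = np.exp(p["log_scale"]), np.exp(p["log_shape"])
        return (shape / scale) * (t / scale) ** (shape - 1.0)
    if family == "weibull_tail":
        lam, b = np.exp(p["log_rate"]), p["shape"]
        return lam * b * t ** (b - 1.0)
    if family == "gompertz":
        return np.exp(p["log_scale"]) * np.exp(p["shape"] * t)
    if family == "loglogistic":
        mu, sigma = p["mu"], p["sigma"]
        z = t * np.exp(-mu)
        num = (1.0 / sigma) * z ** (1.0 / sigma - 1.0) * np.exp(-mu)
        return num / (1.0 + z ** (1.0 / sigma))
    if family == "lognormal":
        mu, sigma = p["mu"], p["sigma"]
        w = (np.log(t) - mu) / sigma
        return np.exp(stats.norm.logpdf(w) - stats.norm.logsf(w)) / (sigma * t)
    if family == "gengamma":
        mu, sigma, q = p["mu"], p["sigma"], p["q"]
        with np.errstate(divide="ignore"):
            w = (np.log(t) - mu) / sigma
        if abs(q) < 1e-8:
            logf = stats.norm.logpdf(w) - np.log(sigma * t)
            logsf = stats.norm.logsf(w)
        else:
            qq = q**-2
            logf = (
                np.log(abs(q))
                - np.log(sigma * t)
                + qq * np.log(qq)
                - special.gammaln(qq)
                + qq * (q * w - np.exp(q * w))
            )
            gx = qq * np.exp(q * w)
            sf = special.gammaincc(qq, gx) if q > 0 else special.gammainc(qq, gx)
            logsf = np.log(np.clip(sf, 1e-300, 1.0))
        return np.exp(logf - logsf)
    raise ValueError(f"unknown family {family!r}")


def _H0_inv(family: str, p: Mapping[str, float], H: np.ndarray) -> np.ndarray:
    """Baseline inverse; returns +inf where the event never occurs."""
    if family == "exponential":
        return H * np.exp(p["log_scale"])
    if family == "weibull":
        return np.exp(p["log_scale"]) * H ** np.exp(-p["log_shape"])
    if family == "weibull_tail":
        return (H * np.exp(-p["log_rate"])) ** (1.0 / p["shape"])
    if family == "gompertz":
        g, c = p["shape"], p["log_scale"]
        if abs(g) < _GOMPERTZ_LINEAR_TOL:
            return H * np.exp(-c)
        arg = g * H * np.exp(-c)
        out = np.full_like(H, np.inf)
        ok = arg > -1.0
        out[ok] = np.log1p(arg[ok]) / g
        return out
    if family == "loglogistic":
        return np.exp(p["mu"]) * np.expm1(H) ** p["sigma"]
    if family == "lognormal":
        return np.exp(p["mu"] + p["sigma"] * stats.norm.isf(np.exp(-H)))
    if family == "gengamma":
        mu, sigma, q = p["mu"], p["sigma"], p["q"]
        sf = np.exp(-H)
        if abs(q) < 1e-8:
            w = stats.norm.isf(sf)
        else:
            qq = q**-2
            gx = special.gammainccinv(qq, sf) if q > 0 else special.gammaincinv(qq, sf)
            w = np.log(gx / qq) / q
        return np.exp(mu + sigma * w)
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# Covariate-adjusted operations
# ---------------------------------------------------------------------------


def cumulative_hazard(model: ParametricHazardModel, t, covariates=None):
    """H(t|x) in cumulative-hazard units (dimensionless)."""
    t = _check_time(t)
    eta = model.linear_predictor(covariates)
    if model.effect_type == "ph":
        return np.exp(eta) * _H0(model.family, model.params, t)
    p = dict(model.params)
    p["mu"] = p["mu"] + eta
    return _H0(model.family, p, t)


def hazard(model: ParametricHazardModel, t, covariates=None):
    t = _check_time(t)
    eta = model.linear_predictor(covariates)
    if model.effect_type == "ph":
        return np.exp(eta) * _h0(model.family, model.params, t)
    p = dict(model.params)
    p["mu"] = p["mu"] + eta
    return _h0(model.family, p, t)


def survival(model: ParametricHazardModel, t, covariates=None):
    """S(t|x) = exp(−H(t|x))."""
    return np.exp(-cumulative_hazard(model, t, covariates))


def inverse_cumulative_hazard(
    model: ParametricHazardModel, H, covariates=None, allow_inf: bool = False
):
    """Smallest t with H(t|x) = H; the right inverse of the cumulative hazard.

    For bounded-hazard families (Gompertz with negative shape) a requested H
    beyond the total hazard means the event never occurs: with
    ``allow_inf=True`` (the sampling path) the corresponding entries are
    ``+inf``; otherwise :class:`EventNeverError` is raised.
    """
    H = np.asarray(H, dtype=float)
    if np.any(H < 0):
        raise ValueError("cumulative hazard must be non-negative")
    eta = model.linear_predictor(covariates)
    scalar = H.ndim == 0
    H = np.atleast_1d(H).astype(float)
    if model.effect_type == "ph":
        t = _H0_inv(model.family, model.params, H * np.exp(-eta))
    else:
        p = dict(model.params)
        p["mu"] = p["mu"] + eta
        t = _H0_inv(model.family, p, H)
    if not allow_inf and np.any(np.isinf(t)):
        raise EventNeverError(
            "requested cumulative hazard exceeds the total hazard H(inf)"
        )
    return float(t[0]) if scalar else t


def hazard_ratio(
    coefficient: float, se: float | None = None, level: float = 0.95
) -> dict[str, float]:
    """exp(β) with a Wald confidence interval exp(β ± z·se)."""
    out = {"hr": float(np.exp(coefficient))}
    if se is not None:
        if se <= 0:
            raise ValueError("standard error must be positive")
        z = stats.norm.ppf(0.5 + level / 2.0)
        out["ci_low"] = float(np.exp(coefficient - z * se))
        out["ci_high"] = float(np.exp(coefficient + z * se))
    return out


def total_hazard(model: ParametricHazardModel, covariates=None) -> float:
    """H(∞|x); finite only for bounded-hazard parameter sets."""
    if model.family == "gompertz" and model.params["shape"] < 0:
        g, c = model.params["shape"], model.params["log_scale"]
        base = np.exp(c) / abs(g)
        if model.effect_type == "ph":
            return float(base * np.exp(model.linear_predictor(covariates)))
        return float(base)
    return float(np.inf)
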