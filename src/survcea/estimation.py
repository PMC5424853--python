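"""Estimators for right-censored, left-truncated transition data.

Contains the nonparametric building blocks (Kaplan–Meier, restricted mean,
Aalen–Johansen cumulative incidence, subject-level bootstrap bands), maximum
likelihood fitting of the parametric hazard families on counting-process
records, fit diagnostics (AIC, Cox–Snell residuals), the state-arrival check
of the Markov assumption, and rate <-> probability conversion.

The parametric likelihood for one transition, with delayed entry, is

    l = sum_i [ d_i * log h(t_i | x_i) - (H(t_i | x_i) - H(e_i | x_i)) ]

where (e_i, t_i, d_i) are the entry time, exit time and event indicator of
record i on that transition's clock.  Maximisation is by direct numerical
optimisation; standard errors come from the numerically differentiated
observed information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess1

from .hazard_models import (
    AFT_FAMILIES,
    _PARAM_KEYS,
    ParametricHazardModel,
    cumulative_hazard,
)

# transition indices of the illness-death model
TRANS_PF_PROG, TRANS_PF_DEATH, TRANS_PROG_DEATH = 1, 2, 3


@dataclass
class TransitionRecord:
    """One counting-process row for a single transition.

    ``tstart``/``tstop`` are on the transition's own clock (study time for
    clock-forward transitions, time since state entry for clock-reset ones);
    ``arrival`` is the study-clock time of entry into the originating state.
    """

    id: int
    trans: int
    tstart: float
    tstop: float
    status: int
    covariates: dict[str, float]
    arrival: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tstop > self.tstart >= 0):
            raise ValueError("need tstop > tstart >= 0")
        if self.status not in (0, 1):
            raise ValueError("status must be 0 or 1")
        if self.trans not in (TRANS_PF_PROG, TRANS_PF_DEATH, TRANS_PROG_DEATH):
            raise ValueError("unknown transition index")


def records_to_frame(records: Iterable[TransitionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "trans": r.trans,
            "tstart": r.tstart,
            "tstop": r.tstop,
            "status": r.status,
            "arrival": r.arrival,
        }
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class KMEstimate:
    """Product-limit estimate: step function with steps at event times."""

    times: np.ndarray  # distinct event times, increasing
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray
    events: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    def evaluate(self, t) -> np.ndarray:
        """S(t) of the step function (right-continuous)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]


def kaplan_meier(
    times: Sequence[float], events: Sequence[int], ci_level: float | None = None
) -> KMEstimate:
    """Product-limit estimator.

    Ties between deaths and censorings at the same recorded time are resolved
    by processing deaths first (censored subjects remain at risk for events
    at their own censoring time).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    uniq = np.unique(times[events == 1])
    n = times.size
    at_risk = np.empty(uniq.size, dtype=int)
    d = np.empty(uniq.size, dtype=int)
    for i, t in enumerate(uniq):
        at_risk[i] = int(np.sum(times >= t))
        d[i] = int(np.sum((times == t) & (events == 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - d / at_risk)
    ci_low = ci_high = None
    if ci_level is not None:
        # Greenwood with log-log transform
        frac = np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.nan)
        var_logs = np.cumsum(frac)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(var_logs) / np.abs(np.log(surv))
            z = stats.norm.ppf(0.5 + ci_level / 2.0)
            ci_low = surv ** np.exp(z * se)
            ci_high = surv ** np.exp(-z * se)
    return KMEstimate(uniq, surv, at_risk, d, ci_low, ci_high)


def km_restricted_mean(km: KMEstimate, horizon: float) -> float:
    """Area under the KM step function up to the horizon (years).

    Beyond the last event time the curve is extended flat at its last value
    (the usual restricted-mean convention).
    """
    if horizon <= 0:
        return 0.0
    knots = np.concatenate([[0.0], km.times, [horizon]])
    vals = np.concatenate([[1.0], km.survival])
    area = 0.0
    for i in range(len(knots) - 1):
        lo, hi = knots[i], min(knots[i + 1], horizon)
        if hi > lo:
            area += vals[min(i, len(vals) - 1)] * (hi - lo)
        if knots[i + 1] >= horizon:
            break
    return float(area)


# ---------------------------------------------------------------------------
# rate <-> probability
# ---------------------------------------------------------------------------


def rate_to_probability(rate: float, cycle: float = 1.0) -> float:
    """p = 1 − exp(−rate·cycle), the constant-hazard conversion."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    return float(-np.expm1(-rate * cycle))


def probability_to_rate(p: float, cycle: float = 1.0) -> float:
    if not 0 <= p < 1:
        raise ValueError("probability must be in [0, 1)")
    return float(-np.log1p(-p) / cycle)


# ---------------------------------------------------------------------------
# Competing risks: Aalen-Johansen cumulative incidence
# ---------------------------------------------------------------------------


def cumulative_incidence(
    times: Sequence[float], event_type: Sequence[int]
) -> dict[int, KMEstimate]:
    """Aalen–Johansen cumulative incidence per cause.

    ``event_type`` uses 0 for censored and positive integers for causes.
    Returns a mapping cause -> step function (stored in KMEstimate containers
    whose ``survival`` field holds the cumulative incidence CI_k(t)).
    """
    times = np.asarray(times, dtype=float)
    event_type = np.asarray(event_type, dtype=int)
    causes = sorted(set(event_type[event_type > 0]))
    uniq = np.unique(times[event_type > 0])
    n_t = uniq.size
    surv_before = np.empty(n_t)  # all-cause S(u-)
    at_risk = np.empty(n_t, dtype=int)
    s = 1.0
    incidences = {k: np.zeros(n_t) for k in causes}
    running = {k: 0.0 for k in causes}
    for i, u in enumerate(uniq):
        nu = int(np.sum(times >= u))
        at_risk[i] = nu
        surv_before[i] = s
        d_all = 0
        for k in causes:
            dk = int(np.sum((times == u) & (event_type == k)))
            running[k] += s * dk / nu
            incidences[k][i] = running[k]
            d_all += dk
        s *= 1.0 - d_all / nu
    return {
        k: KMEstimate(uniq, incidences[k], at_risk, np.zeros(n_t, dtype=int))
        for k in causes
    }


def evaluate_incidence(est: KMEstimate, t) -> np.ndarray:
    """Evaluate a cumulative-incidence step function (0 before first event).

    ``cumulative_incidence`` stores CI_k(t) in KMEstimate containers whose
    natural evaluation starts at 1; incidence curves start at 0 instead.
    """
    t = np.asarray(t, dtype=float)
    idx = np.searchsorted(est.times, t, side="right")
    vals = np.concatenate([[0.0], est.survival])
    return vals[idx]


# ---------------------------------------------------------------------------
# Parametric maximum likelihood
# ---------------------------------------------------------------------------


class FitError(RuntimeError):
    pass


def _pack_init(family: str, tstop, status) -> np.ndarray:
    """Moment-style starting values on the unconstrained optimiser scale."""
    d = max(int(np.sum(status)), 1)
    exposure = float(np.sum(tstop))
    rate = d / max(exposure, 1e-12)
    ev = tstop[status == 1] if np.any(status == 1) else tstop
    if family == "exponential":
        return np.array([-np.log(rate)])
    if family == "weibull":
        return np.array([np.log(np.mean(ev)), 0.0])
    if family == "weibull_tail":
        return np.array([np.log(rate), 0.0])  # (log_rate, log shape)
    if family == "gompertz":
        return np.array([0.0, np.log(rate)])  # (shape, log_scale)
    mu0 = float(np.mean(np.log(ev)))
    s0 = float(np.log(max(np.std(np.log(ev)), 0.1)))
    if family in ("loglogistic", "lognormal"):
        return np.array([mu0, s0])
    if family == "gengamma":
        return np.array([mu0, s0, 1.0])
    raise ValueError(f"unknown family {family!r}")


def _theta_to_params(family: str, theta: np.ndarray) -> dict[str, float]:
    if family == "exponential":
        return {"log_scale": theta[0]}
    if family == "weibull":
        return {"log_scale": theta[0], "log_shape": theta[1]}
    if family == "weibull_tail":
        return {"log_rate": theta[0], "shape": np.exp(theta[1])}
    if family == "gompertz":
        return {"shape": theta[0], "log_scale": theta[1]}
    if family in ("loglogistic", "lognormal"):
        return {"mu": theta[0], "sigma": np.exp(theta[1])}
    if family == "gengamma":
        return {"mu": theta[0], "sigma": np.exp(theta[1]), "q": theta[2]}
    raise ValueError(f"unknown family {family!r}")


def fit_parametric(
    records: pd.DataFrame | Iterable[TransitionRecord],
    family: str,
    covariate_names: Sequence[str] = (),
) -> ParametricHazardModel:
    """Fit one transition's hazard model by maximum likelihood.

    ``records`` is a counting-process frame with columns tstart, tstop,
    status and the covariates; left truncation (tstart > 0) enters through
    H(tstop) − H(tstart).  PH families take covariates on the log-hazard
    scale, AFT families on the location scale.
    """
    if not isinstance(records, pd.DataFrame):
        records = records_to_frame(records)
    tstart = records["tstart"].to_numpy(dtype=float)
    tstop = records["tstop"].to_numpy(dtype=float)
    status = records["status"].to_numpy(dtype=int)
    if status.sum() < 1:
        raise FitError("no events: cannot fit a hazard model")
    X = (
        records[list(covariate_names)].to_numpy(dtype=float)
        if covariate_names
        else np.zeros((len(records), 0))
    )
    n_base = len(_PARAM_KEYS[family])
    is_aft = family in AFT_FAMILIES

    def negloglik(theta: np.ndarray) -> float:
        params = _theta_to_params(family, theta[:n_base])
        betas = theta[n_base:]
        eta = X @ betas if betas.size else np.zeros(len(tstop))
        try:
            m = ParametricHazardModel(family, params)
        except ValueError:
            return np.inf
        from .hazard_models import _H0, _h0  # baseline closed forms

        if is_aft:
            ll = 0.0
            # location shift: evaluate per unique eta for vectorization
            for e in np.unique(eta):
                sel = eta == e
                p = dict(params)
                p["mu"] = p["mu"] + e
                H1 = _H0(family, p, tstop[sel])
                H0_ = _H0(family, p, tstart[sel])
                hz = _h0(family, p, tstop[sel])
                ll += float(
                    np.sum(status[sel] * np.log(np.maximum(hz, 1e-300)))
                    - np.sum(H1 - H0_)
                )
        else:
            H1 = _H0(family, params, tstop)
            H0_ = _H0(family, params, tstart)
            hz = _h0(family, params, tstop)
            ll = float(
                np.sum(status * (np.log(np.maximum(hz, 1e-300)) + eta))
                - np.sum(np.exp(eta) * (H1 - H0_))
            )
        if not np.isfinite(ll):
            return np.inf
        return -ll

    theta0 = np.concatenate([_pack_init(family, tstop, status), np.zeros(X.shape[1])])
    res = optimize.minimize(negloglik, theta0, method="BFGS",
                            options={"maxiter": 300, "gtol": 1e-8})
    if not np.isfinite(res.fun) or not res.success:
        # fall back to a bounded simplex search, then re-polish
        nm = optimize.minimize(negloglik, theta0, method="Nelder-Mead",
                               options={"maxiter": 200 * theta0.size,
                                        "xatol": 1e-6, "fatol": 1e-8})
        polish = optimize.minimize(negloglik, nm.x, method="BFGS",
                                   options={"maxiter": 300, "gtol": 1e-8})
        if np.isfinite(polish.fun) and polish.fun <= min(res.fun, nm.fun):
            res = polish
        elif np.isfinite(nm.fun) and nm.fun < res.fun:
            res = nm
    if not np.isfinite(res.fun):
        raise FitError(f"{family} fit did not converge: {res.message}")
    theta = res.x
    # observed information on the optimiser scale
    se = np.full(theta.size, np.nan)
    try:
        hess = approx_hess1(theta, negloglik)
        cov = np.linalg.inv(hess)
        dd = np.diag(cov)
        se = np.sqrt(np.where(dd > 0, dd, np.nan))
    except np.linalg.LinAlgError:
        pass
    params = _theta_to_params(family, theta[:n_base])
    coeffs = dict(zip(covariate_names, theta[n_base:]))
    coef_se = dict(zip(covariate_names, se[n_base:]))
    param_se = dict(zip(_PARAM_KEYS[family], se[:n_base]))
    return ParametricHazardModel(
        family=family,
        params=params,
        coefficients=coeffs,
        standard_errors=coef_se if covariate_names else None,
        loglik=-float(res.fun),
        param_standard_errors=param_se,
        n_events=int(status.sum()),
    )


def aic(model: ParametricHazardModel) -> float:
    """AIC = −2·loglik + 2·k.

    Note the caveat for transition hazards under competing risks: AIC ranks
    fit to the cause-specific hazard, not to the state-occupancy curves that
    matter downstream, and the comparison is only meaningful within one time
    unit (the likelihood carries a Jacobian under time rescaling).
    """
    if model.loglik is None:
        raise ValueError("model has no stored log-likelihood")
    return -2.0 * model.loglik + 2.0 * model.n_params()


def cox_snell_residuals(
    model: ParametricHazardModel, records: pd.DataFrame, covariate_names=()
) -> pd.DataFrame:
    """r_i = H(tstop_i|x_i) − H(tstart_i|x_i), with the censoring status.

    Under a correctly specified model the residuals behave as a unit
    exponential censored sample: the KM of (r, status) should track exp(−r).
    """
    records = records.reset_index(drop=True)
    tstart = records["tstart"].to_numpy(dtype=float)
    tstop = records["tstop"].to_numpy(dtype=float)
    res = np.empty(len(records))
    if covariate_names:
        key = records[list(covariate_names)].astype(float)
        for _, grp in key.groupby(list(covariate_names)):
            idx = grp.index.to_numpy()
            cov = {k: float(grp.iloc[0][k]) for k in covariate_names}
            res[idx] = cumulative_hazard(model, tstop[idx], cov) - cumulative_hazard(
                model, tstart[idx], cov
            )
    else:
        res = cumulative_hazard(model, tstop) - cumulative_hazard(model, tstart)
    return pd.DataFrame({"residual": res, "status": records["status"].to_numpy()})


# ---------------------------------------------------------------------------
# State-arrival check of the Markov assumption
# ---------------------------------------------------------------------------


def fit_state_arrival_check(
    records: pd.DataFrame,
    covariate_names: Sequence[str] = ("treatment",),
    arrival_col: str = "arrival",
    baseline: str = "cox",
) -> dict[str, float]:
    """Test whether the progression→death hazard depends on arrival time.

    Fits a state-arrival extended model for the 2→3 transition on the study
    clock (delayed entry at the progression time) including the arrival time
    as a covariate, and returns its coefficient, SE and Wald p-value.  A
    coefficient distinguishable from zero is evidence against the Markov
    property.  ``baseline="cox"`` uses a semiparametric Cox fit (Breslow
    ties, lifelines); ``baseline="gompertz"`` uses a parametric baseline.
    """
    if int(records["status"].sum()) < 2:
        raise FitError("fewer than 2 events: arrival check is not identifiable")
    arrival = records[arrival_col].to_numpy(dtype=float)
    if np.ptp(arrival) < 1e-12:
        raise FitError("arrival time is constant across subjects (degenerate)")
    cols = list(covariate_names) + [arrival_col]
    if baseline == "cox":
        from lifelines import CoxPHFitter

        df = records[cols + ["tstart", "tstop", "status"]].copy()
        df["duration"] = df["tstop"]
        cph = CoxPHFitter()
        cph.fit(
            df[cols + ["duration", "status", "tstart"]],
            duration_col="duration",
            event_col="status",
            entry_col="tstart",
        )
        beta = float(cph.params_[arrival_col])
        se = float(cph.standard_errors_[arrival_col])
    elif baseline == "gompertz":
        m = fit_parametric(records, "gompertz", cols)
        beta = m.coefficients[arrival_col]
        se = m.standard_errors[arrival_col]
    else:
        raise ValueError("baseline must be 'cox' or 'gompertz'")
    z = beta / se
    return {
        "beta_arrival": beta,
        "se": se,
        "z": z,
        "p": float(2.0 * stats.norm.sf(abs(z))),
    }


# ---------------------------------------------------------------------------
# Subject-level bootstrap band
# ---------------------------------------------------------------------------


def bootstrap_proportion_ci(
    ipd: pd.DataFrame,
    statistic: Callable[[pd.DataFrame, np.ndarray], np.ndarray],
    grid: np.ndarray,
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Pointwise percentile band for a time→proportion statistic.

    Resamples subjects (rows of the wide IPD table) with replacement within
    treatment arm; ``seed`` is required for reproducibility.
    """
    if seed is None:
        raise ValueError("seed is required (reproducibility contract)")
    rng = np.random.default_rng(seed)
    point = np.asarray(statistic(ipd, grid), dtype=float)
    arms = ipd["arm"].unique()
    groups = {a: ipd[ipd["arm"] == a].reset_index(drop=True) for a in arms}
    draws = np.empty((n_boot, grid.size))
    for b in range(n_boot):
        parts = []
        for a in arms:
            g = groups[a]
            idx = rng.integers(0, len(g), size=len(g))
            parts.append(g.iloc[idx])
        draws[b] = statistic(pd.concat(parts, ignore_index=True), grid)
    alpha = 1.0 - level
    lo = np.quantile(draws, alpha / 2.0, axis=0)
    hi = np.quantile(draws, 1.0 - alpha / 2.0, axis=0)
    return {"grid": grid, "point": point, "low": lo, "high": hi}


def progression_proportion(ipd: pd.DataFrame, grid: np.ndarray) -> np.ndarray:
    """Observed proportion of subjects in the progression state over time."""
    t_prog = ipd["time_prog"].to_numpy(dtype=float)
    end = np.where(
        np.isnan(ipd["time_death"].to_numpy(dtype=float)),
        ipd["time_censor"].to_numpy(dtype=float),
        ipd["time_death"].to_numpy(dtype=float),
    )
    out = np.empty(grid.size)
    for i, t in enumerate(grid):
        out[i] = np.mean((t_prog <= t) & (end > t) & ~np.isnan(t_prog))
    return out


# ---------------------------------------------------------------------------
# IPD reader / long-format converter
# ---------------------------------------------------------------------------

IPD_COLUMNS = ("id", "arm", "time_prog", "time_death", "time_censor")


def read_ipd(path) -> pd.DataFrame:
    """Read wide-format individual patient data.

    Columns: id; arm (0=control/FC, 1=treated/RFC); time_prog (NaN when no
    progression observed); time_death (NaN when alive at last contact);
    time_censor (end of follow-up for subjects without observed death).
    """
    df = pd.read_csv(path)
    missing = [c for c in IPD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"IPD file missing columns {missing}")
    return df


def ipd_to_transition_records(
    ipd: pd.DataFrame, clock_reset_prog_death: bool = True
) -> pd.DataFrame:
    """Wide IPD → counting-process long format, one row per at-risk transition.

    Transitions 1 (PF→Prog) and 2 (PF→Death) run on the study clock from 0 to
    the PF-exit time with cause-specific event indicators.  Transition 3
    (Prog→Death) runs, for subjects who progressed, on the reset clock from 0
    to (death/censor − progression) by default, or on the study clock with
    delayed entry at the progression time when ``clock_reset_prog_death`` is
    False.  ``arrival`` always records the study-clock progression time.
    """
    rows = []
    for _, r in ipd.iterrows():
        prog = r["time_prog"]
        death = r["time_death"]
        cens = r["time_censor"]
        has_prog = not pd.isna(prog)
        has_death = not pd.isna(death)
        end = death if has_death else cens
        pf_exit = prog if has_prog else end
        common = {"id": r["id"], "treatment": float(r["arm"])}
        if pf_exit > 0:
            rows.append(
                dict(common, trans=TRANS_PF_PROG, tstart=0.0, tstop=pf_exit,
                     status=int(has_prog), arrival=0.0)
            )
            rows.append(
                dict(common, trans=TRANS_PF_DEATH, tstart=0.0, tstop=pf_exit,
                     status=int(has_death and not has_prog), arrival=0.0)
            )
        if has_prog and end > prog:
            if clock_reset_prog_death:
                tstart, tstop = 0.0, end - prog
            else:
                tstart, tstop = prog, end
            rows.append(
                dict(common, trans=TRANS_PROG_DEATH, tstart=tstart, tstop=tstop,
                     status=int(has_death), arrival=float(prog))
            )
    return pd.DataFrame(rows)
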