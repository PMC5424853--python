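"""Partitioned survival: occupancy from PFS and OS curves alone.

Progression is not modelled as a transition; its occupancy is the gap
between the overall-survival and progression-free-survival curves
(floored at zero if independent fits cross, with the flooring logged).
Curves come either from the published coefficient set (``build_from_params``)
or from fitting the family menu to individual patient data
(``build_from_ipd``), with the tail-regression procedure applied to OS when
whole-curve extrapolation cannot reach zero by the horizon.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import estimation, extrapolation
from .curves import OccupancyTrace, SurvivalCurve, occupancy_from_curves, reporting_grid
from .hazard_models import FAMILIES, ParametricHazardModel

logger = logging.getLogger(__name__)

SIX_FAMILIES = (
    "exponential",
    "weibull",
    "gompertz",
    "loglogistic",
    "lognormal",
    "gengamma",
)


@dataclass
class PartitionedModel:
    """Per-arm PFS/OS curves and the derived three-state membership."""

    pfs: dict[str, SurvivalCurve]
    os: dict[str, SurvivalCurve]
    membership: dict[str, OccupancyTrace]
    junction_gap: dict[str, float]
    floored: dict[str, bool]
    details: dict | None = None


def build_from_params(
    params: dict,
    horizon: float | None = None,
    step: float = 1.0 / 12.0,
) -> PartitionedModel:
    """Curves from the published coefficient set.

    Control (FC) OS: exponential over the observed period, Weibull tail at
    absolute study time beyond it.  Treated (RFC) OS: the exponential with
    the PH-scaled rate over the observed period, and the control tail mapped
    through the observed-period hazard ratio beyond.  PFS: one Weibull per
    arm over the whole horizon with the PH treatment effect.
    """
    horizon = float(params["horizon"] if horizon is None else horizon)
    times = reporting_grid(horizon, step)
    pfs_model: ParametricHazardModel = params["pfs"]
    os_model: ParametricHazardModel = params["os_observed"]
    tail: ParametricHazardModel = params["os_tail"]
    boundary = params["observed_boundary"]
    hr = params["os_observed_hr"]

    pfs_curves = {
        "fc": SurvivalCurve(times, pfs_model.survival(times, {"treatment": 0}), "pfs fc"),
        "rfc": SurvivalCurve(times, pfs_model.survival(times, {"treatment": 1}), "pfs rfc"),
    }
    fc_os, fc_gap = extrapolation.stitch(
        lambda t: os_model.survival(t, {"treatment": 0}),
        lambda t: tail.survival(t),
        junction=boundary,
        times=times,
        tail_time_mode="absolute",
    )
    fc_os.label = "os fc"
    # RFC: PH-scaled exponential observed, hr-powered FC tail beyond
    rfc_tail = extrapolation.map_by_hazard_ratio(
        SurvivalCurve(times, tail.survival(times)), hr
    )
    rfc_os, rfc_gap = extrapolation.stitch(
        lambda t: os_model.survival(t, {"treatment": 1}),
        lambda t: np.interp(t, rfc_tail.times, rfc_tail.survival),
        junction=boundary,
        times=times,
        tail_time_mode="absolute",
    )
    rfc_os.label = "os rfc"
    os_curves = {"fc": fc_os, "rfc": rfc_os}

    membership, floored = {}, {}
    for arm in ("fc", "rfc"):
        membership[arm], floored[arm] = occupancy_from_curves(
            times, os_curves[arm].survival, pfs_curves[arm].survival
        )
        if floored[arm]:
            logger.warning("OS < PFS crossing floored for arm %s", arm)
    return PartitionedModel(
        pfs=pfs_curves,
        os=os_curves,
        membership=membership,
        junction_gap={"fc": fc_gap, "rfc": rfc_gap},
        floored=floored,
    )


# ---------------------------------------------------------------------------
# IPD route
# ---------------------------------------------------------------------------


def _outcome_tables(ipd: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """PFS and OS (time, status, treatment) tables from wide IPD."""
    death = ipd["time_death"].to_numpy(dtype=float)
    prog = ipd["time_prog"].to_numpy(dtype=float)
    cens = ipd["time_censor"].to_numpy(dtype=float)
    end = np.where(np.isnan(death), cens, death)
    pf_exit = np.where(np.isnan(prog), end, np.fmin(prog, end))
    out = {}
    out["pfs"] = pd.DataFrame(
        {
            "tstart": 0.0,
            "tstop": pf_exit,
            "status": (~np.isnan(prog) | ~np.isnan(death)).astype(int),
            "treatment": ipd["arm"].to_numpy(dtype=float),
        }
    )
    out["os"] = pd.DataFrame(
        {
            "tstart": 0.0,
            "tstop": end,
            "status": (~np.isnan(death)).astype(int),
            "treatment": ipd["arm"].to_numpy(dtype=float),
        }
    )
    return out


def fit_family_menu(
    outcome: pd.DataFrame, families=SIX_FAMILIES
) -> tuple[pd.DataFrame, dict[str, ParametricHazardModel]]:
    """Fit every family to one outcome; return the AIC table and the fits."""
    fits, rows = {}, []
    for fam in families:
        try:
            m = estimation.fit_parametric(outcome, fam, ("treatment",))
        except estimation.FitError as err:
            rows.append({"family": fam, "aic": np.nan, "error": str(err)})
            continue
        fits[fam] = m
        rows.append({"family": fam, "aic": estimation.aic(m), "error": ""})
    table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    if not fits:
        raise estimation.FitError("no family converged")
    return table, fits


def build_from_ipd(
    ipd: pd.DataFrame,
    families=SIX_FAMILIES,
    selection: str = "aic",
    fixed_families: dict[str, str] | None = None,
    horizon: float = 15.0,
    step: float = 1.0 / 12.0,
    zero_tol: float = 0.005,
) -> PartitionedModel:
    """Fit PFS and OS from IPD and partition.

    selection="aic" picks the lowest-AIC family per outcome (diagnostics
    retained in ``details``); selection="fixed" uses ``fixed_families``
    (e.g. {"pfs": "weibull", "os": "exponential"}).  If the selected OS
    extrapolation fails the zero-by-horizon check, the KM-tail regression
    procedure replaces it beyond the selected tail start, with the treated
    arm mapped through the observed-period hazard ratio.
    """
    times = reporting_grid(horizon, step)
    tables = _outcome_tables(ipd)
    details: dict = {"aic": {}, "tail_used": False}
    chosen: dict[str, ParametricHazardModel] = {}
    for outcome in ("pfs", "os"):
        table, fits = fit_family_menu(tables[outcome], families)
        details["aic"][outcome] = table
        if selection == "fixed":
            fam = (fixed_families or {}).get(outcome)
            if fam is None:
                raise ValueError("selection='fixed' needs fixed_families entries")
            chosen[outcome] = fits[fam]
        elif selection == "aic":
            chosen[outcome] = fits[table.iloc[0]["family"]]
        else:
            raise ValueError("selection must be 'aic' or 'fixed'")
    details["models"] = chosen
    details["cox_snell"] = {
        k: estimation.cox_snell_residuals(m, tables[k], ("treatment",))
        for k, m in chosen.items()
    }

    pfs_curves = {
        arm: SurvivalCurve(
            times, chosen["pfs"].survival(times, {"treatment": x}), f"pfs {arm}"
        )
        for arm, x in (("fc", 0), ("rfc", 1))
    }

    os_model = chosen["os"]
    gaps = {"fc": 0.0, "rfc": 0.0}
    if os_model.survival(horizon, {"treatment": 0}) > zero_tol:
        # whole-curve extrapolation fails the zero-by-horizon check: tail path
        details["tail_used"] = True
        fc = tables["os"][tables["os"]["treatment"] == 0]
        km = estimation.kaplan_meier(fc["tstop"], fc["status"])
        start = extrapolation.select_tail_start(km, "weibull", horizon, zero_tol)
        if start is None:
            warnings.warn("no qualifying tail start; whole-curve fit retained")
            details["tail_used"] = False
        else:
            tail = extrapolation.fit_tail(km, start, "weibull")
            details["tail_fit"] = tail
            # observed-period treatment HR from the fitted OS model
            hr = float(np.exp(os_model.coefficients["treatment"]))
            fc_curve, gaps["fc"] = extrapolation.stitch(
                lambda t: os_model.survival(t, {"treatment": 0}),
                tail, junction=start, times=times,
            )
            rfc_tail = SurvivalCurve(times, tail.survival(times) ** hr)
            rfc_curve, gaps["rfc"] = extrapolation.stitch(
                lambda t: os_model.survival(t, {"treatment": 1}),
                lambda t: np.interp(t, rfc_tail.times, rfc_tail.survival),
                junction=start, times=times,
            )
            os_curves = {"fc": fc_curve, "rfc": rfc_curve}
    if not details["tail_used"]:
        os_curves = {
            arm: SurvivalCurve(
                times, os_model.survival(times, {"treatment": x}), f"os {arm}"
            )
            for arm, x in (("fc", 0), ("rfc", 1))
        }

    membership, floored = {}, {}
    for arm in ("fc", "rfc"):
        membership[arm], floored[arm] = occupancy_from_curves(
            times, os_curves[arm].survival, pfs_curves[arm].survival
        )
        if floored[arm]:
            logger.warning("OS < PFS crossing floored for arm %s", arm)
    return PartitionedModel(
        pfs=pfs_curves,
        os=os_curves,
        membership=membership,
        junction_gap=gaps,
        floored=floored,
        details=details,
    )
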