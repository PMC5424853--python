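"""Nonparametric estimators, parametric MLE and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from survcea import estimation
from survcea.estimation import (
    FitError,
    bootstrap_proportion_ci,
    cox_snell_residuals,
    cumulative_incidence,
    fit_parametric,
    fit_state_arrival_check,
    ipd_to_transition_records,
    kaplan_meier,
    km_restricted_mean,
    probability_to_rate,
    rate_to_probability,
)
from survcea.hazard_models import ParametricHazardModel


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


class TestKaplanMeier:
    def test_toy_product_limit(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [1, 0, 1])
        # S = 2/3 on [1, 3), 0 from 3 (hand product-limit (2/3)*(0/1))
        assert km.evaluate(1.5) == pytest.approx(2.0 / 3.0)
        assert km.evaluate(2.9) == pytest.approx(2.0 / 3.0)
        assert km.evaluate(3.0) == pytest.approx(0.0)
        assert km.evaluate(0.5) == pytest.approx(1.0)

    def test_all_censored_and_single_death(self):
        km = kaplan_meier([1.0, 2.0], [0, 0])
        assert km.evaluate(5.0) == pytest.approx(1.0)
        km1 = kaplan_meier([2.0], [1])
        assert km1.evaluate(1.9) == 1.0 and km1.evaluate(2.0) == 0.0

    def test_deaths_precede_censorings_at_ties(self):
        # censored subject at t=1 is still at risk for the death at t=1
        km = kaplan_meier([1.0, 1.0, 2.0], [1, 0, 0])
        assert km.evaluate(1.0) == pytest.approx(2.0 / 3.0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(size=200)
        km = kaplan_meier(t, np.ones(200, dtype=int))
        grid = np.quantile(t, [0.1, 0.5, 0.9])
        for g in grid:
            assert km.evaluate(g) == pytest.approx(np.mean(t > g), abs=1e-12)

    def test_against_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(7)
        t = rng.weibull(1.4, 300) * 2.0
        c = rng.uniform(0.5, 3.0, 300)
        obs = np.minimum(t, c)
        status = (t <= c).astype(int)
        km = kaplan_meier(obs, status)
        kmf = KaplanMeierFitter().fit(obs, status)
        grid = np.linspace(0.1, 2.5, 9)
        ours = km.evaluate(grid)
        theirs = kmf.survival_function_at_times(grid).to_numpy()
        assert np.allclose(ours, theirs, atol=1e-10)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])


class TestRestrictedMean:
    def test_step_areas(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [1, 0, 1])
        assert km_restricted_mean(km, 3.0) == pytest.approx(1 + 2 * (2 / 3))

    def test_flat_curve(self):
        km = kaplan_meier([5.0], [0])
        assert km_restricted_mean(km, 2.0) == pytest.approx(2.0)

    def test_half_rectangle(self):
        km = kaplan_meier([1.0, 1.0], [1, 0])
        # S = 1 on [0,1), 1/2 on [1, 2)
        assert km_restricted_mean(km, 2.0) == pytest.approx(1.5)


# ---------------------------------------------------------------------------
# rate <-> probability
# ---------------------------------------------------------------------------


def test_rate_probability_conversion():
    # inverse of the 24.1791-month post-progression KM mean, monthly cycle
    assert rate_to_probability(1.0 / 24.1791) == pytest.approx(0.0405, abs=5e-5)
    assert rate_to_probability(0.0) == 0.0
    assert rate_to_probability(probability_to_rate(0.3)) == pytest.approx(0.3)
    with pytest.raises(ValueError):
        probability_to_rate(1.0)


# ---------------------------------------------------------------------------
# Competing risks
# ---------------------------------------------------------------------------


class TestCumulativeIncidence:
    def test_single_cause_equals_one_minus_km(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(size=100)
        e = rng.integers(0, 2, 100)
        ci = cumulative_incidence(t, e)[1]
        km = kaplan_meier(t, e)
        grid = np.linspace(0.05, 3.0, 11)
        assert np.allclose(
            estimation.evaluate_incidence(ci, grid), 1.0 - km.evaluate(grid),
            atol=1e-12,
        )

    def test_five_subject_hand_computation(self):
        # frozen from a hand Aalen-Johansen: times 1..5,
        # causes (1, 2, censored, 1, 2)
        ci = cumulative_incidence([1, 2, 3, 4, 5], [1, 2, 0, 1, 2])
        assert ci[1].evaluate(1.0) == pytest.approx(0.2)
        assert ci[2].evaluate(2.0) == pytest.approx(0.2)
        assert ci[1].evaluate(4.0) == pytest.approx(0.5)  # 0.2 + 0.6/2
        assert ci[2].evaluate(5.0) == pytest.approx(0.5)  # 0.2 + 0.3
        assert ci[1].evaluate(5.0) + ci[2].evaluate(5.0) == pytest.approx(1.0)

    def test_no_events(self):
        assert cumulative_incidence([1.0, 2.0], [0, 0]) == {}

    def test_sum_equals_one_minus_allcause_km(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(size=300)
        e = rng.choice([0, 1, 2], 300, p=[0.3, 0.4, 0.3])
        cis = cumulative_incidence(t, e)
        km = kaplan_meier(t, (e > 0).astype(int))
        grid = np.linspace(0.01, 4.0, 23)
        total = sum(estimation.evaluate_incidence(c, grid) for c in cis.values())
        assert np.allclose(total, 1.0 - km.evaluate(grid), atol=1e-12)

    def test_against_lifelines_aalen_johansen(self):
        from lifelines import AalenJohansenFitter

        rng = np.random.default_rng(13)
        t = rng.exponential(size=150)
        e = rng.choice([0, 1, 2], 150, p=[0.2, 0.5, 0.3])
        ours = cumulative_incidence(t, e)[1]
        ajf = AalenJohansenFitter(calculate_variance=False).fit(t, e, event_of_interest=1)
        idx = ajf.cumulative_density_.index.to_numpy()
        vals = ajf.cumulative_density_.iloc[:, 0].to_numpy()
        grid = np.quantile(t[e > 0], [0.2, 0.5, 0.8])
        # right-continuous step lookup (lifelines stores step points)
        theirs = vals[np.searchsorted(idx, grid, side="right") - 1]
        assert np.allclose(estimation.evaluate_incidence(ours, grid), theirs, atol=1e-8)


# ---------------------------------------------------------------------------
# Parametric MLE
# ---------------------------------------------------------------------------


def _exp_frame(rng, n, rate, censor=None):
    t = rng.exponential(1.0 / rate, n)
    if censor is None:
        return pd.DataFrame(
            {"tstart": 0.0, "tstop": t, "status": 1, "treatment": 0.0}
        )
    return pd.DataFrame(
        {
            "tstart": 0.0,
            "tstop": np.minimum(t, censor),
            "status": (t <= censor).astype(int),
            "treatment": 0.0,
        }
    )


class TestFitParametric:
    def test_exponential_matches_events_over_exposure(self):
        rng = np.random.default_rng(21)
        df = _exp_frame(rng, 5000, 0.5)
        m = fit_parametric(df, "exponential")
        closed = df["status"].sum() / df["tstop"].sum()
        assert np.exp(-m.params["log_scale"]) == pytest.approx(closed, rel=1e-6)
        # and within 3 SE of the truth
        se_rate = closed / np.sqrt(df["status"].sum())
        assert abs(np.exp(-m.params["log_scale"]) - 0.5) < 3 * se_rate

    def test_exponential_with_censoring(self):
        rng = np.random.default_rng(22)
        df = _exp_frame(rng, 3000, 0.5, censor=2.0)
        m = fit_parametric(df, "exponential")
        closed = df["status"].sum() / df["tstop"].sum()
        assert np.exp(-m.params["log_scale"]) == pytest.approx(closed, rel=1e-6)

    def test_weibull_shape_ci_covers_one_on_exponential_data(self):
        rng = np.random.default_rng(23)
        df = _exp_frame(rng, 2000, 0.7)
        m = fit_parametric(df, "weibull")
        k, se = m.params["log_shape"], m.param_standard_errors["log_shape"]
        assert abs(k) < 3 * se  # log-shape 0 <=> shape 1

    def test_gompertz_recovery_from_trial_records(self, trial_ipd):
        long = ipd_to_transition_records(trial_ipd)
        sub = long[long["trans"] == 1]
        m = fit_parametric(sub, "gompertz", ("treatment",))
        assert abs(m.params["shape"] - 0.474) < 3 * m.param_standard_errors["shape"]
        assert (
            abs(m.params["log_scale"] - (-2.187))
            < 3 * m.param_standard_errors["log_scale"]
        )
        # generating treatment effect is the printed HR 0.572
        assert abs(m.coefficients["treatment"] - np.log(0.572)) < 3 * (
            m.standard_errors["treatment"]
        )

    def test_all_censored_raises(self):
        df = pd.DataFrame({"tstart": 0.0, "tstop": [1.0, 2.0], "status": 0})
        with pytest.raises(FitError):
            fit_parametric(df, "exponential")

    def test_left_truncation_split_invariance(self):
        """Splitting records at interior times leaves the fit unchanged.

        The likelihood factorises over disjoint at-risk intervals, so a
        record (0, t] is equivalent to (0, t/2] censored plus (t/2, t].
        """
        rng = np.random.default_rng(31)
        df = _exp_frame(rng, 800, 0.4, censor=3.0)
        half = df["tstop"] / 2.0
        split = pd.concat(
            [
                pd.DataFrame(
                    {"tstart": 0.0, "tstop": half, "status": 0, "treatment": 0.0}
                ),
                pd.DataFrame(
                    {
                        "tstart": half,
                        "tstop": df["tstop"],
                        "status": df["status"],
                        "treatment": 0.0,
                    }
                ),
            ],
            ignore_index=True,
        )
        for family in ("exponential", "gompertz"):
            m_whole = fit_parametric(df, family)
            m_split = fit_parametric(split, family)
            for key, val in m_whole.params.items():
                assert m_split.params[key] == pytest.approx(val, abs=1e-5)


class TestDiagnostics:
    def test_aic_formula(self):
        m = ParametricHazardModel(
            "gompertz",
            {"shape": 0.1, "log_scale": -2.0},
            coefficients={"treatment": 0.2},
            loglik=-100.0,
        )
        assert estimation.aic(m) == pytest.approx(206.0)  # 3 parameters

    def test_cox_snell_residuals_are_unit_exponential(self):
        rng = np.random.default_rng(41)
        df = _exp_frame(rng, 2000, 0.6, censor=3.0)
        m = fit_parametric(df, "exponential")
        res = cox_snell_residuals(m, df)
        km = kaplan_meier(
            np.maximum(res["residual"], 1e-12), res["status"].to_numpy()
        )
        grid = np.linspace(0.05, 1.5, 10)
        assert np.max(np.abs(km.evaluate(grid) - np.exp(-grid))) < 0.05

    def test_aic_shift_under_time_rescaling_is_family_independent(self):
        """Rescaling time shifts every family's AIC by the same Jacobian.

        The log-likelihood changes by -d*log(c) for any hazard family when
        time is multiplied by c, so AIC differences BETWEEN families are
        invariant; only absolute AICs are scale-dependent.
        """
        rng = np.random.default_rng(43)
        df = _exp_frame(rng, 500, 0.5, censor=3.0)
        df12 = df.copy()
        df12[["tstart", "tstop"]] *= 12.0  # years -> months
        d = df["status"].sum()
        for family in ("exponential", "weibull"):
            a_years = estimation.aic(fit_parametric(df, family))
            a_months = estimation.aic(fit_parametric(df12, family))
            assert a_months - a_years == pytest.approx(2 * d * np.log(12), rel=1e-4)


# ---------------------------------------------------------------------------
# State-arrival check
# ---------------------------------------------------------------------------


def _arrival_records(seed, n, beta_arrival):
    """Progression->death records with a true arrival-time effect."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(0.2, 2.0, n)
    rate = 0.5 * np.exp(beta_arrival * a)
    dur = rng.exponential(1.0 / rate)
    fup = np.maximum(4.0 - a, 0.01)
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "trans": 3,
            "tstart": a,
            "tstop": a + np.minimum(dur, fup),
            "status": (dur <= fup).astype(int),
            "arrival": a,
            "treatment": rng.integers(0, 2, n).astype(float),
        }
    )


def _markov_null_records(seed, n):
    """Clock-forward generation: the death hazard ignores arrival time."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(0.2, 2.0, n)
    tdeath = a + rng.exponential(size=n) / 0.3
    tstop = np.minimum(tdeath, 4.0)
    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "trans": 3,
            "tstart": a,
            "tstop": tstop,
            "status": (tdeath <= 4.0).astype(int),
            "arrival": a,
            "treatment": rng.integers(0, 2, n).astype(float),
        }
    )
    return df[df["tstop"] > df["tstart"]]


class TestStateArrivalCheck:
    def test_null_rejection_rate_near_nominal(self):
        rejections = sum(
            fit_state_arrival_check(_markov_null_records(s, 300))["p"] < 0.05
            for s in range(40)
        )
        assert rejections <= 8  # 5% nominal; binomial slack at 40 replicates

    def test_power_against_arrival_effect(self):
        rejections = sum(
            fit_state_arrival_check(_arrival_records(s, 1000, 0.5))["p"] < 0.05
            for s in range(10)
        )
        assert rejections >= 8

    def test_parametric_baseline_recovers_effect(self):
        out = fit_state_arrival_check(
            _arrival_records(0, 800, 0.5), baseline="gompertz"
        )
        assert out["beta_arrival"] == pytest.approx(0.5, abs=3 * out["se"])

    def test_degenerate_arrival_raises(self):
        df = _arrival_records(1, 200, 0.0)
        df["arrival"] = 1.0
        df["tstart"] = 1.0
        with pytest.raises(FitError):
            fit_state_arrival_check(df)


# ---------------------------------------------------------------------------
# Bootstrap band
# ---------------------------------------------------------------------------


class TestBootstrapBand:
    def test_requires_seed(self, trial_ipd):
        with pytest.raises(ValueError):
            bootstrap_proportion_ci(
                trial_ipd, estimation.progression_proportion, np.array([1.0]), 10
            )

    def test_degenerate_data_zero_width(self):
        ipd = pd.DataFrame(
            {
                "id": range(20),
                "arm": 0,
                "time_prog": 1.0,
                "time_death": np.nan,
                "time_censor": 4.0,
            }
        )
        band = bootstrap_proportion_ci(
            ipd, estimation.progression_proportion, np.array([0.5, 2.0]), 50, seed=1
        )
        assert np.allclose(band["low"], band["high"])

    def test_band_contains_point_estimate(self, trial_ipd):
        grid = np.linspace(0.25, 3.5, 8)
        band = bootstrap_proportion_ci(
            trial_ipd, estimation.progression_proportion, grid, n_boot=200, seed=4
        )
        assert np.all(band["low"] <= band["point"] + 1e-12)
        assert np.all(band["high"] >= band["point"] - 1e-12)

    def test_coverage_of_true_proportion(self, msm_spec):
        """Band covers the model-implied progression occupancy at t=2."""
        from survcea import multistate_semimarkov as msm
        from survcea.synthetic_data import TrialDesign, simulate_trial

        spec, _ = msm_spec
        truth = msm.occupancy_numeric(spec).prog[24]  # t = 2 years
        design = TrialDesign(
            spec=spec, n_treated=1, n_control=200, accrual_years=1.0
        )
        grid = np.array([2.0])
        covered = 0
        n_rep = 30
        for s in range(n_rep):
            ipd = simulate_trial(design, seed=500 + s)
            ipd = ipd[ipd["arm"] == 0]
            band = bootstrap_proportion_ci(
                ipd, estimation.progression_proportion, grid, n_boot=200, seed=s
            )
            covered += band["low"][0] <= truth <= band["high"][0]
        assert covered >= int(0.85 * n_rep)
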