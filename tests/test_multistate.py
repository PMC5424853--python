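"""Semi-Markov illness-death model: grids, simulation, convolution oracle."""

import numpy as np
import pytest

from survcea.hazard_models import ParametricHazardModel
from survcea.multistate_semimarkov import (
    T12,
    T13,
    T23,
    GridRefinementError,
    MultiStateSpec,
    apply_treatment,
    build_hazard_grid,
    occupancy_numeric,
    refined_grid,
    simulate_paths,
)


def constant_spec(a=0.2, b=0.05, c=0.4, clock23="reset"):
    def gomp(rate):
        return ParametricHazardModel(
            "gompertz", {"shape": 0.0, "log_scale": np.log(rate)}
        )

    return MultiStateSpec(
        models={T12: gomp(a), T13: gomp(b), T23: gomp(c)},
        clocks={T12: "forward", T13: "forward", T23: clock23},
    )


def three_state_constant_occupancy(a, b, c, t):
    """Closed-form occupancy under constant hazards (clock irrelevant)."""
    t = np.asarray(t, dtype=float)
    pf = np.exp(-(a + b) * t)
    if abs(a + b - c) < 1e-12:
        prog = a * t * np.exp(-c * t)
    else:
        prog = a / (c - a - b) * (np.exp(-(a + b) * t) - np.exp(-c * t))
    return pf, prog


class TestHazardGrid:
    def test_monthly_grid_fails_after_nine_years(self, msm_spec):
        """The rising progression hazard makes monthly ΔH reach 1 late on.

        This is precisely why the late part of the horizon needs 1/144-year
        increments before path probabilities can be formed.
        """
        spec, _ = msm_spec
        coarse = refined_grid(15.0, refine_after=15.0)  # monthly throughout
        with pytest.raises(GridRefinementError, match="finer grid"):
            build_hazard_grid(spec, grid=coarse)
        # closed form: ΔH over [14, 14+1/12] is far above 1
        dH = spec.H(T12, 14 + 1 / 12) - spec.H(T12, 14.0)
        assert dH > 1.0
        assert dH == pytest.approx(7.27, abs=0.05)

    def test_refined_grid_passes(self, msm_spec):
        spec, _ = msm_spec
        out = build_hazard_grid(spec)
        grid = out["grid"]
        assert np.all(out[T12] < 1.0)
        # the first refined interval after 9 years is ~1/144 year wide
        i9 = int(np.argmin(np.abs(grid - 9.0)))
        assert grid[i9 + 1] - grid[i9] == pytest.approx(1 / 144)
        # late fine-grid increments stay below one but not by much
        assert out[T12].max() > 0.5

    def test_exponential_increments_constant(self):
        spec = constant_spec(0.1, 0.0001, 0.2)
        out = build_hazard_grid(spec, grid=refined_grid(15.0, refine_after=15.0))
        assert np.allclose(out[T12], 0.1 / 12, rtol=1e-9)

    def test_decreasing_hazard_has_decreasing_increments(self):
        m = ParametricHazardModel("gompertz", {"shape": -0.487, "log_scale": -2.825})
        spec = MultiStateSpec(
            models={T12: m, T13: m, T23: m},
            clocks={T12: "forward", T13: "forward", T23: "reset"},
        )
        out = build_hazard_grid(spec, grid=refined_grid(15.0, refine_after=15.0))
        assert np.all(np.diff(out[T13]) < 0)


class TestSimulatePaths:
    def test_seed_is_required(self, msm_spec):
        with pytest.raises(ValueError, match="seed"):
            simulate_paths(msm_spec[0], n_paths=10)

    def test_no_progression_degenerates_to_single_survival(self):
        spec = constant_spec(a=1e-12, b=0.3, c=0.4)
        trace = simulate_paths(spec, n_paths=20000, seed=3)
        assert np.all(trace.prog == 0.0)
        expected = np.exp(-0.3 * trace.times)
        tol = 3 * np.maximum(trace.mc_se["pf"], 1e-12) + 1e-9
        assert np.all(np.abs(trace.pf - expected) <= np.maximum(tol, 3e-3))

    @pytest.mark.parametrize("clock23", ["reset", "forward"])
    def test_constant_hazard_closed_form(self, clock23):
        """At t=2 the occupancy matches the competing-risks convolution."""
        spec = constant_spec(0.2, 0.05, 0.4, clock23)
        trace = simulate_paths(spec, n_paths=50000, seed=4, horizon=5.0)
        pf_true, prog_true = three_state_constant_occupancy(0.2, 0.05, 0.4, 2.0)
        i = int(np.argmin(np.abs(trace.times - 2.0)))
        assert abs(trace.pf[i] - pf_true) < 3 * trace.mc_se["pf"][i]
        assert abs(trace.prog[i] - prog_true) < 3 * trace.mc_se["prog"][i]

    def test_determinism_under_fixed_seed(self, msm_spec):
        spec, _ = msm_spec
        t1 = simulate_paths(spec, n_paths=2000, seed=9)
        t2 = simulate_paths(spec, n_paths=2000, seed=9)
        assert np.array_equal(t1.prog, t2.prog)

    def test_grid_method_bias_shrinks_with_refinement(self, msm_spec):
        """|grid − exact| is smaller on the 1/144 grid than on 1/12."""
        spec, _ = msm_spec
        exact = occupancy_numeric(spec, horizon=15.0)
        coarse_grid = refined_grid(15.0, refine_after=9.0)  # paper's grid
        fine_grid = refined_grid(15.0, fine=1 / 144, refine_after=0.0)
        err = {}
        for name, grid in (("coarse", coarse_grid), ("fine", fine_grid)):
            tr = simulate_paths(
                spec, n_paths=50000, seed=5, method="grid", grid=grid
            )
            err[name] = np.max(np.abs(tr.prog - exact.prog))
        assert err["fine"] < err["coarse"]

    def test_exact_simulator_matches_convolution_oracle(self, msm_spec):
        """Path fractions track the deterministic oracle for both arms."""
        spec, hrs = msm_spec
        for arm_spec, seed in ((spec, 123), (apply_treatment(spec, hrs), 124)):
            oracle = occupancy_numeric(arm_spec)
            trace = simulate_paths(arm_spec, n_paths=100000, seed=seed)
            for state in ("pf", "prog", "dead"):
                diff = np.max(np.abs(getattr(trace, state) - getattr(oracle, state)))
                assert diff < 3 * trace.mc_se[state].max()


class TestOccupancyNumeric:
    def test_progression_free_closed_form(self, msm_spec):
        spec, _ = msm_spec
        trace = occupancy_numeric(spec)
        i = int(np.argmin(np.abs(trace.times - 4.0)))
        H12 = spec.H(T12, 4.0)
        H13 = spec.H(T13, 4.0)
        assert H12 == pytest.approx(1.3403, abs=1e-4)
        assert H13 == pytest.approx(0.1044, abs=1e-4)
        assert trace.pf[i] == pytest.approx(np.exp(-H12 - H13), rel=1e-10)
        assert trace.pf[i] == pytest.approx(0.2358, abs=1e-4)

    def test_starts_at_progression_free(self, msm_spec):
        trace = occupancy_numeric(msm_spec[0])
        assert (trace.pf[0], trace.prog[0], trace.dead[0]) == (1.0, 0.0, 0.0)

    def test_constant_hazard_agreement_with_closed_form(self):
        spec = constant_spec(0.2, 0.05, 0.4)
        trace = occupancy_numeric(spec, horizon=5.0)
        pf_true, prog_true = three_state_constant_occupancy(
            0.2, 0.05, 0.4, trace.times
        )
        assert np.max(np.abs(trace.pf - pf_true)) < 1e-10
        assert np.max(np.abs(trace.prog - prog_true)) < 1e-6

    def test_absorbing_progression_equals_cause_incidence(self):
        """With no 2->3 hazard, P_prog is the 1->2 cumulative incidence."""
        from scipy.integrate import quad

        spec = constant_spec(0.3, 0.1, 1e-12)
        trace = occupancy_numeric(spec, horizon=5.0)
        for t in (1.0, 3.0, 5.0):
            ci, _ = quad(lambda u: np.exp(-0.4 * u) * 0.3, 0.0, t)
            i = int(np.argmin(np.abs(trace.times - t)))
            assert trace.prog[i] == pytest.approx(ci, abs=1e-6)


class TestApplyTreatment:
    def test_unit_ratios_leave_occupancy_unchanged(self, msm_spec):
        spec, _ = msm_spec
        same = apply_treatment(spec, {T12: 1.0, T13: 1.0, T23: 1.0})
        a = occupancy_numeric(spec, horizon=5.0)
        b = occupancy_numeric(same, horizon=5.0)
        assert np.array_equal(a.prog, b.prog)

    def test_published_ratio_matches_coefficient(self):
        # exp(0.342) = 1.408 to printed precision
        assert np.exp(0.342) == pytest.approx(1.408, abs=2e-3)

    def test_doubling_hazard_squares_latent_survival(self, msm_spec):
        spec, _ = msm_spec
        doubled = apply_treatment(spec, {T12: 2.0})
        t = np.linspace(0.1, 10.0, 20)
        assert np.allclose(
            np.exp(-doubled.H(T12, t)), np.exp(-spec.H(T12, t)) ** 2, rtol=1e-12
        )

    def test_invalid_ratio(self, msm_spec):
        with pytest.raises(ValueError):
            apply_treatment(msm_spec[0], {T12: -1.0})
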