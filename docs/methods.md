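# Methods

`survcea` estimates survival-based effectiveness — discounted Life Years
(LY) and quality-adjusted life years (QALYs) — for a three-state
progression-free (PF) / progression / death disease model, by three routes
that are standard in health technology assessment, and makes the routes
comparable on identical valuation settings. The case study built into the
fixtures is a two-arm first-line chronic lymphocytic leukemia trial
(rituximab + fludarabine + cyclophosphamide, "RFC", vs fludarabine +
cyclophosphamide, "FC"; 408 vs 409 patients, up to four years of follow-up)
whose published regression coefficients are transcribed in
`survcea/fixtures/*.yaml`. All times are in years; the monthly model cycle
is 1/12 year.

## Hazard families

Six parametric families are supported for transition and outcome hazards —
exponential, Weibull, Gompertz, log-logistic, log-normal, generalized gamma
— plus the "tail" reparametrization of the Weibull,
S(t) = exp(−e^a·t^b), used when a curve tail is fitted by linearized
regression. Conventions that matter:

- **Exponential** `log_scale` c gives rate λ = e^(−c) (so the published
  overall-survival c = 2.753 means λ ≈ 0.0637/year).
- **Weibull (fitted form)** S(t) = exp(−(t/e^s)^(e^k)) with `log_scale` s and
  `log_shape` k.
- **Gompertz** hazard h(t) = e^c·e^(g·t) with `shape` g and `log_scale` c;
  H(t) = e^c/g·(e^(g·t) − 1). "Scale" is therefore a log baseline rate. With
  g < 0 the total hazard is bounded by e^c/|g| and a fraction of subjects
  never experience the event — the inverse cumulative hazard then returns
  +inf (sampling) or raises (strict mode). This reading of the published
  shape/log(scale) pairs is the one under which the published multi-state
  LY/QALY table is numerically reproducible; the alternative (scale as a
  time scale) is not.
- **AFT families** (log-logistic, log-normal, generalized gamma) take
  covariates as a location shift of μ on log time; PH families scale the
  cumulative hazard by e^(βx). The generalized gamma uses the (μ, σ, Q)
  parametrization with Q = 1 ≡ Weibull and Q → 0 ≡ log-normal (both are
  regression-tested).

Every family exposes closed-form survival, hazard, cumulative hazard and
inverse cumulative hazard (the generalized gamma inverts through the
regularized incomplete-gamma inverse), which is what makes exact path
simulation cheap.

## Estimation

Kaplan–Meier, restricted means and Aalen–Johansen cumulative incidence are
implemented directly (ties: deaths before censorings) and cross-checked in
the tests against lifelines. Parametric transition models are fitted by
maximising

l = Σᵢ dᵢ·log h(tᵢ|xᵢ) − (H(tᵢ|xᵢ) − H(eᵢ|xᵢ))

on counting-process records with delayed entry eᵢ, using BFGS with a
bounded Nelder–Mead fallback; standard errors come from the numerically
differentiated observed information (on the optimiser scale: log-shape,
log-σ). This deliberately avoids tying the package to any one
survival-fitting backend; the exponential events/exposure closed form and
a left-truncation factorisation identity (splitting records at interior
times leaves estimates unchanged) pin the likelihood down in tests.

The Markov assumption is probed with a state-arrival extended model for
progression→death on the study clock: a Cox fit (lifelines, Breslow ties,
delayed entry at the progression time) including arrival time as a
covariate; a Gompertz-baseline parametric variant is available. The check
reports the coefficient, SE and Wald p only — model choice stays with the
analyst. A subject-level bootstrap (resampling within arm, seed mandatory)
provides pointwise percentile bands for observed state proportions.

AIC is reported per transition fit, with the caveat (tested) that under
competing risks it ranks cause-specific-hazard fit, not the state-occupancy
curves of interest, and that time-unit rescaling shifts every family's AIC
by the same Jacobian 2·d·log c, leaving between-family differences
unchanged.

## Partitioned survival

PF occupancy is the PFS curve; progression occupancy is OS − PFS; death is
1 − OS. In coefficients mode the published fits are used directly: PFS is a
single Weibull per arm (PH treatment effect e^(−0.519)); control-arm OS is
the exponential over the observed period [0, 3.6] and the tail Weibull
(a = −4.377, b = 2.257) beyond, evaluated at **absolute study time**;
treated-arm OS applies the observed-period hazard ratio 0.753 — as a rate
multiplier before 3.6 years, and as S^0.753 of the control tail after.
Absolute-time tail evaluation is the default because it is continuous with
the observed fit (junction step ≈ 0.003) and reaches ≈0.0035 at 15 years;
measuring tail time from the tail start would force S = 1 at the junction.
Junction discontinuities are reported, never repaired (an optional
conditional-survival renormalisation exists, off by default).

Because OS and PFS are modelled independently they can cross; progression
occupancy is floored at zero with the occurrence logged. On the bundled
coefficients the crossing is a few 1e-4 near t = 0 in the RFC arm only
(the Weibull PFS hazard starts at zero, the exponential OS hazard does
not) and moves the discounted areas by <1e-3 LY.

In IPD mode all six families are fitted per outcome with AIC tables and
Cox–Snell diagnostics retained; if the selected OS model's extrapolation
fails the zero-by-horizon check (S(15) > `zero_tol`, default 0.005 — no
Weibull is exactly zero at finite time), the KM-tail procedure takes over:
candidate tail starts are the unique event times, each tail is an
unweighted OLS on the transformed step points (one point per distinct
event time; S∈{0,1} points dropped with a warning), and the **latest**
start whose extrapolation reaches ≈0 by the horizon wins.

## Markov cohort (manufacturer-style)

A monthly-cycle three-state cohort with a priori transition rules:
progression→death uses the constant monthly probability
1 − exp(−1/24.1791) ≈ 0.0405 (inverse of the post-progression KM restricted
mean, both arms); PF→death uses the observed monthly probability (0.0012
RFC, 0.00139 FC) or an age-specific background monthly probability
1 − (1−q_annual)^(1/12), whichever is larger; staying in PF is the monthly
conditional survival of the same PFS Weibull as the partitioned model.
Background mortality is **off by default** (the published analysis's life
table and cohort age are not in the fixtures; any CSV with age and annual
probability can be supplied; cohort start age defaults to 61 and is purely
a configuration default). No half-cycle correction is applied: occupancy
is integrated by the same trapezoid as every other route. Because the
progression→death probability is constant, clock-reset and clock-forward
bookkeeping coincide (regression-tested with a layered cohort), and as the
cycle shrinks the cohort LY converges to the continuous-time value
(tested at 1/12 → 1/192-year cycles against the convolution oracle).

With background mortality off, this route's arm totals are *not* expected
to match the published 5.73/4.65 (which depended on an age-specific life
table); its PF increment (1.18 LY) does match, since it shares the PFS
Weibull with the partitioned route.

## Semi-Markov multi-state model

The continuous-time illness-death model fits each transition directly:
Gompertz baselines (fixtures transcribe the published per-transition
shape/log-scale), clock-forward for PF→progression and PF→death,
clock-reset for progression→death, treatment as per-transition hazard
ratios. The printed ratios (0.572 / 0.710 / 1.408) are the default;
`use_printed_hr=False` switches to exp(coefficient) where the two disagree
in the source.

State occupancy comes from two engines:

- **Path simulation** (`simulate_paths`) reproduces the published
  mechanism. The default "exact" method draws each latent transition time
  by inverting its cumulative hazard at unit-exponential deviates
  (competing latent times for the two PF exits; reset-clock duration added
  to the progression time). The "grid" method steps a discrete grid where
  each transition fires with probability equal to its cumulative-hazard
  increment — this requires every increment below one, which the rising
  PF→progression Gompertz violates on a monthly grid beyond ~9 years
  (ΔH ≈ 7 over [14, 14+1/12]); the grid therefore refines from 1/12 to
  1/144 year after 9 years, and `build_hazard_grid` raises a named error
  when increments still reach one. Only 1/12-year points enter the
  trapezoid regardless of internal refinement. Occupancy traces carry
  per-point binomial Monte-Carlo SEs; a seed is mandatory, one stream per
  arm.
- **Deterministic convolution** (`occupancy_numeric`):
  P_PF(t) = exp(−H₁₂(t)−H₁₃(t)),
  P_Prog(t) = ∫₀ᵗ P_PF(u)·h₁₂(u)·exp(−H₂₃ over (u,t]) du
  by composite trapezoid on a 1/144-year grid (verified against
  adaptive quadrature to ~2e-7 and against closed forms for constant
  hazards). This is the simulator's oracle and the default prediction
  engine where no Monte-Carlo noise is wanted.

The grid method carries an O(Δ) bias (events land at interval ends) that
shrinks under refinement (tested); the exact method is unbiased and agrees
with the oracle within three Monte-Carlo SEs per state at 10⁵ paths.

## Economics

LY per state is the trapezoid integral of occupancy times the pointwise
discount factor (1+r)^(−t) on the uniform 1/12-year grid (r = 0.035/year,
horizon 15 years); QALYs weight PF time by 0.8 and progression time by
0.6. Discounting before integration, with annual-rate compounding, is the
convention under which the published tables reproduce to their printed
precision. Observed/extrapolated splits at any (snapped-to-grid) boundary
are additive to machine precision. ICERs (Δcost/Δeffect, treated −
control) accept per-arm total costs from configuration; published ICERs
were computed from unrounded intermediates and are deliberately not
machine targets.

## Synthetic trials

`synthetic_data.simulate_trial` emulates the case-study design: 408/409
per arm, uniform accrual over one year, administrative cutoff four years
after trial start (individual follow-up 3–4 years), no other loss to
follow-up by default (optional exponential dropout). Event times come from
the semi-Markov Gompertz model by inverse-cumulative-hazard sampling with
the proper clocks, so refitting recovers the generating parameters
(3-SE coverage tested at trial size and at 2000/arm) and post-progression
survival is stationary in arrival time (KS-tested). What the generator
does **not** emulate: the real trial's accrual pattern (unknown — under
the assumed 3–4-year follow-up the model implies ~250 observed control-arm
progressions, more than the trial reported, so printed event counts are a
plausibility band only), covariates beyond arm, and interval-censored
assessment times. Passing recovery tests therefore validate the fitting
machinery under the model's own assumptions, not the model's fit to the
original data.

## Test scale choices

Simulation-backed tests run at sizes chosen to keep the default suite
under ~20 s while leaving clear statistical margins: simulator-vs-oracle
checks at 5×10⁴–10⁵ paths (per-state max deviation vs 3× max MC SE),
state-arrival null at 40 replicates of n=300 and power at 10 replicates of
n=1000, bootstrap coverage at 30 replicates × 200 resamples, PFS
family-selection recovery at 12 replicates (Weibull must be the modal and
majority winner — its generalized-gamma superset caps the attainable
selection rate well below certainty). The acceptance script uses 2×10⁵
paths per arm, putting its Monte-Carlo SE an order of magnitude below the
~0.06 LY noise the original 5000-path analysis carried.

## Known limitations

- No spline/cure-fraction hazards, frailties, tunnel states, or
  interval-censored fitting; the state graph is fixed to illness-death.
- No probabilistic sensitivity analysis or bootstrapped
  transition-probability bands (the surfaces needed to add them — seeded
  samplers, per-transition fits with SEs — are exposed).
- Costs enter only as per-arm totals; no cost model is included.
- The Markov-cohort route reproduces the manufacturer's mechanism, not
  their exact numbers, absent their life table and cohort age.
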