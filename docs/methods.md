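# Methods

This note records the statistical model behind `nphtest`, the conventions
and numerical choices the implementation fixes, what the synthetic-data
generators do and do not emulate, and the package's known limitations.

## Estimands and estimators

**RMST.** For a survival time T and horizon t\*, μ(t\*) = E[min(T, t\*)]
= ∫₀^t\* S(t) dt. The estimator integrates the Kaplan–Meier step function
exactly. Two variances are available:

- *asymptotic* (default): Var(μ̂) = Σᵢ A(tᵢ)² dᵢ / (nᵢ(nᵢ − dᵢ)) over event
  times tᵢ ≤ t\*, with A(tᵢ) = ∫_{tᵢ}^{t\*} Ŝ(u) du — the Greenwood-type
  form. Terms with nᵢ = dᵢ contribute nothing (A = 0 there).
- *jackknife*: (n−1)/n Σⱼ (μ̂₍₋ⱼ₎ − μ̄)², matching the usual nonparametric
  RMST estimator, at O(n²) cost.

The default is the asymptotic form because the permutation test evaluates
hundreds of thousands of RMST scans; on exponential samples of n = 200 the
two SEs agree with a bootstrap SE within 15 % (tested). The variance method
is recorded in every result object.

Conventions fixed here: tied events and censorings at the same time are
resolved events-first (standard product-limit); μ̂ is not estimable beyond
the largest uncensored event time and the public `rmst` refuses such
horizons, but inside a two-arm scan the arm that does not contain the
largest *pooled* event time is integrated with its last survival value
carried forward (the alternative — failing on every scan — would make the
grid's upper endpoint unusable; the carry-forward is flagged).

**The horizon grid.** n_t = 10 equally spaced horizons on the raw time
scale from the 30th centile of the pooled uncensored event times to the
largest pooled event time, endpoints included. The 30th-centile lower bound
avoids the early-follow-up region where an RMST difference is unstable and
clinically unrepresentative. The centile uses linear interpolation between
order statistics; pooled (not per-arm) event times are used. Both choices
are conventions the package fixes and logs rather than options the data
could whipsaw. Ties in the maximal statistic resolve to the smallest
maximizing horizon.

**Cox and logrank.** The Cox model has the binary arm as its only
covariate; the one-dimensional partial likelihood is maximized by Newton
iteration (tolerance 1e−10 on the step, 50-iteration cap, steps clipped to
±5 for stability far from the optimum). Breslow's tie convention is the
default because it makes the score test at β = 0 algebraically identical to
the logrank statistic on tie-free data — an equivalence the test suite uses
as an oracle; Efron's convention is available and is cross-checked against
`lifelines`. Monotone likelihoods (all events in one arm) raise rather than
returning a pseudo-estimate. All P-values are two-sided.

**Grambsch–Therneau.** The classic 1-df score statistic
d·V⁻¹·[Σ(gₖ−ḡ)rₖ]²/Σ(gₖ−ḡ)², with rₖ the raw Schoenfeld residuals, V the
observed information and gₖ a transform of the event time — identity
(default), rank, or 1 − KM. The default transform is the untransformed
time; the transform is reported in the result because the statistic is not
invariant to it (only affine transforms leave it unchanged). R's current
`cox.zph` weights each event by its own risk-set variance instead of the
average information per event; on a 120-subject fixture the two agree to
about 1 % and the suite pins that agreement.

## The combined test

C_max is the maximal standardized-RMST-difference chisquare over the grid.
Its naive 1-df tail probability P_max ignores the maximization, so it is
calibrated in one of two ways:

1. **Exact permutation.** M random reassignments of the arm labels
   (preserving arm sizes), the grid held fixed at the observed one;
   P_perm = (N + 0.5)/(M + 1) with N = #{Cᵢ > C_max} (strict inequality;
   ties count as non-exceedances). Resolution 0.5/(M+1); M = 999 by default
   (resolution 0.0005), larger for definitive analyses. One seeded
   generator per call, seed recorded.
2. **Closed-form approximation.** P_perm ≈ 1.762·P_max^0.885 −
   0.802·P_max^2.547 for P_max ≤ 0.85, else the plateau 0.9963, clamped to
   [0, 1]. The coefficients are fixed calibration constants (a Box–Tidwell
   fit of exact-permutation results against P_max on simulated null
   trials). Evaluating the printed curve at 0.85 gives ≈ 0.9958, not
   0.9963 — the published coefficients are rounded — and the plateau value
   is honored as calibrated, accepting the ~5e−4 jump at the truncation
   point. `estimate_beta_b` and `CalibrationConstants` let users
   re-calibrate on their own null simulations; re-calibration on this
   package's synthetic nulls is not expected to reproduce the shipped
   constants exactly, and the shipped values are the operative defaults.

P_min = min(P_Cox, P_perm) is referred to a Beta(1, 1.5) null:
P_comb = 1 − (1 − P_min)^1.5. Under independence the correct reference
would be Beta(1, 2) (Bonferroni in the limit); b = 1.5 credits the strong
positive correlation between the two component P-values. Consequently
P_min ≤ P_comb ≤ 1.5·P_min, with the factor 1.5 attained as P_min → 0, and
the level-α P_min cutoff is 1 − (1 − α)^(2/3).

Calibration evidence computed by this package's own suite: over 2000
simulated null trials (n = 500, ~40 % administrative censoring) the
empirical type 1 errors of P_Cox, P_perm and P_comb lie within binomial
3 SE of nominal at α ∈ {0.01, 0.05, 0.10}, and across 100 null replicates
the exact (M = 999) and approximate permutation P-values have Spearman
correlation above 0.9.

## Simulation engine

`RPModel` is a flexible parametric survival model: a restricted cubic
spline s(x) in x = ln t for the log cumulative hazard, ln H(t) = s(ln t).
Fitting maximizes Σ_events [s(xᵢ) + ln s′(xᵢ) − xᵢ] − Σ_all exp(s(xⱼ)) with
an analytic gradient (BFGS, gradient tolerance 1e−7), started from a least
squares fit to the log Nelson–Aalen curve; nonpositive spline slopes at
event times are pushed away by a quadratic penalty, and the fitted
cumulative hazard is verified nondecreasing on a 200-point grid before a
model is returned. Knots: boundary at the min/max log event time, interior
at equally spaced centiles (df = 3 → 33rd/67th), the common
flexible-parametric placement. Sampling inverts s(ln t) = ln(−ln U):
closed-form in the linear tails beyond the boundary knots, vectorized
bisection (1e−10 in ln t) inside.

Censoring is modelled by refitting with the event indicator reversed, on
the pooled sample (no arm distinction); degenerate cases fall back to a
point mass (single administrative cutoff) or a "no censoring" sentinel.
`UniformAccrualCensoring(A, T)` expresses staggered entry directly:
C = T − U(0, A).

Scenarios:

- **A (null):** one sample from the control model split at random 1:1 —
  exchangeability makes any valid test exact here.
- **B (PH):** the research arm adds ln HR (default ln 0.75) to the spline
  intercept, multiplying the hazard by HR exactly.
- **C (early effect):** independent control and research models. The canned
  pair targets a research hazard 0.5× control before the control median and
  1.2× after, smoothed by least squares projection of the piecewise log
  cumulative hazard onto the spline basis; the smoothed hazard-ratio curve
  rises from ≈ 0.45 through 1 around 5 median-scale time units.
- **D (late effect):** ln H₁ = ln H₀ + c(ln t) with the decreasing logistic
  c(x) = −θ·expit((x − ln t₀)/τ); HR(t) = e^c (1 + c′/s₀′) analytically.
  Defaults θ = 0.4, t₀ = 3.2, τ = 0.22 were calibrated once, against the
  default exponential control (rate 0.25/year, median ≈ 2.8 years — a
  typical advanced-cancer overall-survival scale), so that |HR − 1| < 0.02
  for t ≤ 1 year and HR < 0.8 by year 3. Parameter sets implying a
  nonpositive hazard anywhere are rejected with the offending time.

The default study conditions used throughout testing: null fixtures are
identical unit-rate exponential arms with an administrative horizon of
ln 2.5 (≈ 40 % censoring) at 250 per arm; scenario-based runs use the
exponential(0.25) control with uniform accrual over 4 years and analysis at
year 8 (≈ 30 % censoring). Replicate counts are 2000 for type 1 error and
500 for power comparisons, with 10,000-draw single replicates where only a
point estimate is needed; these desk-scale sizes give binomial/Monte-Carlo
error small enough for every bound the tests assert.

What the generators emulate: realistic event-time shapes (monotone or
bending hazards), administrative censoring from staggered entry, and the
four canonical effect patterns. What they do not: covariate structure,
dependent or informative censoring, delayed entry, cure fractions, or the
idiosyncrasies of any particular historical trial. Passing tests therefore
demonstrate calibration and power ordering under clean randomized-trial
conditions, not robustness to data pathologies.

## Design calculations

Control survival tabulated on a grid is interpolated
piecewise-exponentially (constant hazard per interval; exponential through
(0, 1)→(t₁, S₁) before the first point); linear-in-S interpolation is an
option and moves results at the ±1-patient level. Event probabilities
integrate S_arm(T − u) over uniform entry u with quadrature split at the
interpolation kinks (tolerance 1e−8).

Two events formulas:

- **noncentrality** (default): the logrank score's mean and variance are
  integrated exactly, letting the research-arm share of the risk set drift
  from the allocation fraction as the arms deplete at different rates;
  n solves (z_{1−α/2} + z_pow)²·V/E², patients = ⌈n⌉, reported events =
  round(patients · P̄). This convention reproduces the reference worked
  example — (763, 509) at (0.05, 0.90), (843, 562) at (0.0336, 0.90),
  (816, 544) at (0.0336, 0.89) — exactly, which is why it is the default.
- **schoenfeld**: the textbook closed form divided by P̄, patients rounded
  up to an even integer; typically one or two patients fewer.

The combined-test design substitutes α′ = 1 − (1 − α)^(2/3) and power −1
percentage point (the plain substitution overshoots the target power by
about a point), then reuses the ordinary machinery; adjusted designs are
never smaller than unadjusted ones over the tested (α, power) grid.
A simulation cross-check (piecewise-exponential arms at the designed n,
uniform accrual, 2000 replicates) recovers the nominal logrank power within
2.5 points.

## Degenerate inputs and tie-breaks

- Grid construction fails when the 30th centile equals the largest event
  time (all events tied); the GT test fails when all events share one time.
- Permutation replicates needing carry-forward beyond the observed scan's
  extrapolation are counted in `n_flagged` (rare: label permutation
  preserves the pooled event-time set).
- Fixture censoring that would produce a zero observed time is clamped to
  the smallest positive float; times are otherwise never rescaled — the
  time unit is the caller's responsibility throughout.
- `t_opt` is the smallest maximizing grid time; study replicates failing a
  test precondition are tallied separately, never dropped silently.

## Limitations

- Single binary covariate only: no adjustment, stratification, or
  multi-arm designs; no delayed entry/left truncation.
- The closed-form permutation approximation and b = 1.5 are fixed
  calibration constants; for data very unlike the calibration conditions
  the exact permutation path is the safeguard (`exact_perm_M`).
- The design module assumes uniform accrual, no loss to follow-up, and a
  1:1-style allocation handled through a single proportion; weighted
  logrank alternatives and the related one-sided tests are out of scope.
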