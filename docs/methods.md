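# Methods

## Model

Each individual `i` carries a latent pair `(U0i, U1i)` and a structural noise
`Ei ~ Exp(1)`. The potential-outcome hazard under exposure `a ∈ {0, 1}` is

    λ_i^a(t) = f0(t, U0i) + U1i · g(t) · a,

and the potential event time `T_i^a` solves `Λ_i^a(T_i^a) = Ei` with
`Λ_i^a(t) = ∫₀ᵗ λ_i^a(s) ds` (inverse-cumulative-hazard sampling). Exposure
is randomized, `A_i ~ Bernoulli(π)` independent of `(U0, U1, E)`; the factual
record is `(min(T_i^{A_i}, C_i), status, A_i)` with optional independent
censoring (none by default — the estimand-level analyses need none; the Aalen
module handles censored inputs regardless).

Supported baseline families (`ell ≥ 0` a hazard offset, `U0 ≥ 0`):

| family | `f0(t, u0)` | `Λ0(t)` |
|---|---|---|
| `constant` | `ell + u0` | `(ell + u0) t` |
| `quadratic` | `ell + u0 t²` | `ell t + u0 t³/3` |
| `scaled_quadratic` | `ell + u0 t²/20` | `ell t + u0 t³/60` |

The effect profile `g` defaults to 1 (`G(t) = t`), i.e. a time-invariant
individual effect; an arbitrary `(g, G)` pair may be supplied, in which case
event times come from a bracketed scalar root-finder instead of closed forms.

Hazard positivity is enforced at construction with the sufficient condition
`ess-inf_{t,u0} f0 ≥ −min(0, min-support(U1)) · sup g`: for the quadratic
families the infimum is `ell` (at `t = 0`), for the constant family
`ell + min-support(U0)`.

**Coupling of the two potential outcomes.** One shared `Ei` feeds both arms,
so `(T⁰, T¹)` are comonotone given the latents and individual-level
contrasts are well defined (with `u1 ≥ 0`, `T¹ ≤ T⁰` surely). All
implemented estimands depend only on the marginal laws of `T⁰` and `T¹`,
which any admissible coupling shares; a test verifies the marginal
invariance by re-simulating with independent per-arm noises.

## Latent laws and dependence

- `BHNModifier(p1, μ1, p2, μ2)`: three-point Benefit(μ1 ≤ 0)/Harm(μ2 ≥ 0)/
  Neutral(0) law. The harm-only case can be written as `p1 = 0` or `μ1 = 0`;
  both encode the same law and a test asserts their curves coincide.
- `ShiftedGammaModifier(shape, scale, shift)`: `U1 = G − shift`,
  `G ~ Gamma(shape, scale)`. **Gamma convention:** `Gamma(shape, scale)` with
  mean `shape·scale` everywhere in the package; the unit case
  shape = scale = 1 (the standard exponential, mean 1 on the hazard scale)
  is where both textbook conventions coincide, so the choice only matters
  for users who change these parameters.
- `GammaFrailty`, `DegenerateFrailty`, `DegenerateModifier` complete the set;
  degenerate laws give the effect-homogeneous / frailty-free special cases.

Laplace transforms are closed-form per law (three-point sum with
log-sum-exp guarding, `e^{c·shift}(1+c·scale)^{−shape}` for the shifted
gamma — finite only for `c·scale > −1`, enforced). A Monte-Carlo transform
exists as a cross-check only.

Dependence between `U0` and `U1` uses a Gaussian copula with
`ρ = sin(π τ/2)` from Kendall's τ. The boundaries `τ = ±1` are implemented
as deterministic monotone/antitone quantile couplings (the bivariate normal
is degenerate there); `τ = 0` draws independent uniforms. No other copula
families are supported.

## Estimands

- `chd(scm, t) = E[U1]·g(t)`.
- Analytic `smchd(scm, t)` requires `τ = 0` (the two baseline survivor terms
  then cancel exactly) and returns `−L′(G(t))/L(G(t)) · g(t)`; requesting it
  under dependence raises. Tilted means and the closed-form integrated BHN
  curve `B(t) = −log(p1(e^{−tμ1}−1) + p2(e^{−tμ2}−1) + 1)` subtract the
  dominant exponent before exponentiating, so `t` up to 1e6 is safe.
- "Limiting" values are operationalized as evaluation at a large time
  (t = 100–200 in the tests and acceptance script, tolerance 1e−3), plus the
  exact limit helper `survivor_mean_limit` returning the smallest support
  point with positive mass — the exponential tilt concentrates there.
- The observed hazard difference of a randomized trial has no separate
  operation: within this package's RCT-only scope it equals the SMCHD, and
  that equality is exercised end-to-end (Aalen fit on simulated data vs the
  analytic integrated SMCHD) rather than duplicated as code.

## Monte-Carlo SMCHD

For dependent latents the three survivor terms are estimated from **one**
shared cohort of `n` potential-outcome samples across the whole time grid
(re-simulating per time point would add independent noise at every `t` and
roughen the curve). Integration is a left-endpoint Riemann sum with step 0.1
— the left endpoint makes `B(0) = 0` exact; step and horizon are
configurable. Pointwise standard errors combine the three conditional-mean
sampling variances in quadrature (conservative: it ignores their positive
correlations, which shrink the variance of the difference) and propagate
through the Riemann sum. When the risk set of a conditioning arm empties the
grid is truncated with a warning, never extrapolated. Grid cells of a τ×ℓ
experiment get independent seeds derived from the base seed; common random
numbers across cells are not used by default.

Default study conditions: `n = 10,000`, step 0.1,
τ ∈ {−1, −0.5, 0, 0.5, 1}, ℓ ∈ {0, 0.5, 1}, quadratic baseline with
`U0 ~ Gamma(1,1)` and `U1 + ℓ ~ Gamma(1,1)`. Curve checks in the tests use a
horizon of t_max = 3–5: beyond that the exposed risk set of the quadratic
family is nearly empty at n = 10,000, and the landmark comparisons (e.g. the
gap ordering at t = 2) sit well inside the horizon.

## Aalen additive-hazards estimator

At each ordered event time, with `X` the at-risk design (intercept column
first), the increment `(XᵀX)⁻¹Xᵀ dN` is added to the cumulative regression
functions and `diag((XᵀX)⁻¹Xᵀ diag(dN) X (XᵀX)⁻¹)` to their variances (the
optional-variation martingale estimator; no robust variant). Numerical
choices:

- Ties are processed in a single step with a multi-one `dN` — equivalent to
  summed per-subject increments against the same risk set, hence invariant
  to order within the tie.
- Subjects censored exactly at an event time stay in that time's risk set
  ("censoring after events").
- Estimation stops (recording `stop_time_`) when `cond(XᵀX) > 1e10`; no
  regularization, matching the classical estimator. A singular design at the
  first event time is an error.
- Curves are right-continuous step functions, 0 at `t = 0`; bands are
  pointwise normal, `estimate ± z_{(1+level)/2}·sqrt(variance)`.
- For time-fixed covariates, `XᵀX` at every event time is accumulated from
  suffix sums of per-subject outer products over subjects sorted by time —
  algebraically identical to re-assembling the risk set each time, but
  `O(n log n + E p²)`, which keeps the 100-replicate coverage test cheap.

The per-time coverage check uses the standard empirical-coverage statistic:
the fraction of (replicate, landmark-time) pairs whose pointwise 95% band
contains the true line, required ≥ 0.90.

## What the synthetic data does and does not emulate

The generator produces exactly the study conditions above: RCT assignment,
additive hazards, frailty/modifier laws with known Laplace transforms,
optional independent censoring. It does **not** emulate confounded
assignment, covariate-dependent censoring, time-varying covariates,
measurement error in event times, or the institutional/site structure of
real oncology trials — the shipped "case-study analog" is a synthetic stand-in
for a real trial's workflow, not a re-analysis of any trial's data. Passing
tests therefore demonstrate correctness of the estimands, simulator and
estimator under the model's own assumptions, not robustness to their
violation; in particular the selection-signature result shows what an
analyst *would* see if the additive SCM held, which is exactly the
identifiability warning the package illustrates.

## Known limitations

- Analytic SMCHD only under independence; dependent cases are Monte-Carlo
  with the stated error bars.
- Gaussian copula only; archimedean families are out of scope.
- The Aalen module handles time-fixed covariates; time-varying designs,
  weighted/ridge variants and the Lin–Ying restriction are out of scope, as
  are hypothesis tests for a zero coefficient.
- Confidence bands are pointwise, not simultaneous.
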