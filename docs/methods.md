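# Methods

This note documents the statistical models, algorithms and numerical choices
behind `ipdmasim`, and what its synthetic-data experiments can and cannot
show.

## Data-generating process

Two-level data: subjects nested in `K` studies.  Exposure `x` is
Bernoulli(0.5) per subject, recoded −½/+½ so that the intercept is the
log-odds at the *average* of the two arms and the slope is the log odds
ratio.  The outcome is Bernoulli with

* random-intercept mode: `logit π = (β₀ + b₀ⱼ) + (β₁ + b₁ⱼ)x`, with
  `(b₀ⱼ, b₁ⱼ)` bivariate normal, variances `τ₀², τ₁²`, correlation `ρ`;
* stratified mode: `logit π = βⱼ + (β₁ + b₁ⱼ)x`, with `βⱼ` uniform and
  `b₁ⱼ ~ N(0, τ₁²)`.

**Uniform intercept range.** The stratified mode only requires "a uniform
distribution"; we centre it at `β₀` with half-width `τ₀√3`, so the mean and
variance equal those of the normal study effects and the two modes are
moment-matched — a comparison between them then isolates the distributional
shape, not its scale.

**Study sizes.** Balanced: `round(N/K)` each.  Imbalanced: `round(0.25K)`
"large" studies of size `round(10s)` and the rest of size `round(s)`, with
`s = N/(K_small + 10·K_large)` and round-half-to-even throughout.  For
(K, N) = (5, 500), (15, 500), (15, 3000) this yields large-study sizes of
357, 98 and 588 with small studies of 36, 10 and 59.  Small studies come
first in the dataset (a fixed convention).

**Defaults.** `β₀ = −0.85` (a 30% conditional outcome rate), `β₁ = 0.18`
(odds ratio ≈ 1.2, a realistic trial effect), variances from
{0.05, 1, 4} — I² ≈ 0.01, 0.23, 0.55 under `τ²/(τ² + π²/3)` —
`ρ ∈ {0, 0.5}` and 1000 Monte-Carlo repetitions per scenario.  Sensitivity
settings (e.g. a 5% outcome rate via `β₀ = logit(0.05) ≈ −2.944`, or
K = 50 with N = 9000) are ordinary configuration values, not special cases.

**Seeding.** Each scenario carries a master seed (assigned from its position
when a grid is built); replicate `r` uses the child stream
`SeedSequence([scenario.seed, r])`.  Results are therefore independent of
execution order, scenario ordering and worker count, and any single
replicate can be regenerated in isolation.

## Estimators

### First stage (two-stage methods)

Per-study logistic regression of `y` on `x`.  With a single binary covariate
the model is saturated, so the ML fit equals the 2×2-table closed form; the
implementation runs IRLS on the two aggregated binomial cells and the test
suite verifies the identity.  Tables with a zero cell receive the
Haldane–Anscombe correction (0.5 to all four cells, flagged per study), so
the first stage always returns finite estimates; a study with an entirely
missing arm is dropped as unusable with a message.

### DerSimonian–Laird (two-stage)

Cochran's Q with fixed-effect weights gives the method-of-moments
between-study variance, truncated at zero; pooling uses random-effects
weights `1/(v̂ⱼ + τ̂₁²)`.  Non-iterative, always "converged", and no
interval for `τ̂₁²` is produced.

### Bivariate REML (two-stage)

The per-study pairs `(γ̂₀ⱼ, γ̂₁ⱼ)` are modelled as
`N((γ₀, γ₁), Σ + Cⱼ)` with `Cⱼ` the first-stage covariance.  The REML
log-likelihood is maximized over `Σ` parameterized by its Cholesky factor
(guaranteeing positive semidefiniteness), with two starts (0.1·I and a
moment estimate); fixed effects come from GLS at `Σ̂`, `SE(β̂₁)` from the
GLS information, and `SE(τ̂₁²)` from the numerically differentiated REML
Hessian in natural (variance) coordinates.  Individual entries of `Σ` can be
held fixed, which is how the test suite reduces the model to univariate REML
for an independent grid-search comparison.

### One-stage GLMMs

Both one-stage models are fit on per-(study, arm) aggregated binomial cells
— likelihood-identical to the subject-level data for a binary exposure and
roughly two orders of magnitude faster in the Monte-Carlo loops.

**PQL** follows the penalized quasi-likelihood scheme: linearize to the
working response `z = η + (y − μ)/(μ(1−μ))` with weights `μ(1−μ)`
(aggregated over cells), fit the working linear mixed model
`z = Xβ + Zu + ε`, `ε ~ N(0, W⁻¹)` by REML, update `η` from the GLS fixed
effects and BLUPs, and repeat until every fixed-effect and variance
parameter moves by less than 1e-8 (cap 100 iterations).  The residual scale
is held at 1 (binomial variance); variants that estimate an extra dispersion
parameter (e.g. `MASS::glmmPQL`) give slightly different answers.
`SE(β̂₁)` is the GLS standard error at convergence; `SE(τ̂₁²)` the inverse
curvature of the final working REML objective.  A fit is non-converged when
the cap is hit, the inner REML fails, or the estimated random-effects
covariance has an eigenvalue below 1e-8 (the boundary / non-positive-definite
rule).

**AGHQ** maximizes the marginal likelihood directly.  The likelihood
factorizes over studies; each study's 2-D (random intercept + slope) or 1-D
(random slope) integral is approximated by Gauss–Hermite quadrature
recentered at the study's conditional mode and rescaled by the curvature
there, computed by a vectorized, step-halving Newton iteration.  With one
node per dimension the approximation *is* the Laplace approximation (tested
to 1e-10).  The number of nodes per dimension starts at 5 and doubles (cap
41) until the re-maximized log-likelihood moves by less than 1e-4; a fixed
node count can be requested instead.  For the stratified model the `K` fixed
intercepts are profiled out study-by-study inside each likelihood
evaluation, keeping the outer optimization two-dimensional.  Standard errors
come from the numerically differentiated observed information in natural
coordinates; a non-positive-definite information matrix marks the fit
non-converged.

**Optimization.** Variance-component objectives (inner REML, bivariate REML,
AGHQ) are smooth and 1–5 dimensional; they are minimized by a safeguarded
Newton iteration on central finite differences (eigenvalue-shifted Hessians,
backtracking, gradient-descent fallback), which reaches the 1e-8-level
parameter precision the convergence criteria require.  Random-effect
covariances are always optimized through their Cholesky factors; a 1e-10
ridge keeps densities proper at near-boundary iterates.

## Assessment criteria

For each target parameter (β₁ and τ₁²): bias = mean(θ̂) − θ over finite
estimates; MSE and RMSE; Gaussian coverage — a replicate covers iff
|θ̂ − θ| ≤ 1.96·SE(θ̂), boundary inclusive — as a percentage of replicates
with a usable SE; and the convergence rate n_converged / n_attempted.
Non-converged replicates keep their finite estimates in bias/MSE (failed
fits are data); non-finite estimates are excluded and counted.  Coverage of
τ₁² is computed on the variance scale with the same 1.96 rule (no log
transform) and is undefined for DL.  Because scenario-level tables in this
literature are often displayed as "median (p25, p75)" cells whose underlying
population is ambiguous, the summary reports **both** the absolute mean bias
and the median/quartiles of the per-replicate absolute error, so either
aggregation can be compared.

## What the generator does and does not emulate

It reproduces the stated two-level design exactly: Bernoulli(½) exposure,
logistic outcome, normal (or uniform-intercept) study effects, balanced or
25%-large/10× imbalanced sizes.  It does not include confounders, more than
two arms, non-normal random slopes, missingness, or any within-study
covariate structure — so passing tests demonstrate estimator behaviour under
a correctly specified hierarchical logistic model, not robustness to
real-data violations of it.

## Known limitations and observed behaviour

* With `ρ = 0.5` and large heterogeneity, inverse-variance weights correlate
  with the realized study effects (studies whose outcome rate is nearer ½
  are both more precise and, on average, have larger effects), giving the
  two-stage DL pooled estimate a genuine positive bias of roughly 0.05 on
  the log-OR scale in the small-sample scenarios.  This is a property of the
  estimator under this generating process, reproduced identically by an
  independent meta-analysis implementation on the same tables.
* Wald intervals for τ₁² under-cover badly in small samples for all methods
  that provide them — the known failure mode of normal-theory intervals for
  variance components.
* Boundary variance estimates are frequent at K = 15 with small studies;
  they are flagged through the non-positive-definite rule and depress the
  one-stage convergence rates, as expected.
* The stratified-intercept AGHQ fit (profiled intercepts with a bounded
  scalar search per study) is accurate but slow; it is intended for modest
  `K`, not for large Monte-Carlo sweeps.
* Monte-Carlo sizes in the packaged checks are 300–1000 replicates per
  scenario (the framework's own choice of problem size); the full
  multi-thousand-cell grid is run through the harness's checkpointed
  `run_experiment`.
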