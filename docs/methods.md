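# Methods

## Estimands

We consider a binary baseline exposure `X`, a mediator `M_t` and an
outcome `Y_t` measured at waves `t = 1..T` (`M_t` immediately before
`Y_t`). The exposure is conceptually decomposed into a mediator
component `X^M`, whose only direct descendants are the mediators, and
an outcome component `X^Y`, acting directly only on the outcome
process. In observed data `X ≡ X^M ≡ X^Y`; the decomposition defines
the estimands

- **SDE_t** (separable direct effect):
  `E[Y_t(X^Y=x, X^M=x')] − E[Y_t(X^Y=x', X^M=x')]`
- **SIE_t** (separable indirect effect):
  `E[Y_t(X^Y=x, X^M=x)] − E[Y_t(X^Y=x, X^M=x')]`

with default contrast `x = 1, x' = 0`. Setting both components to the
same level reproduces the ordinary intervention on `X`, so
SDE_t + SIE_t telescopes to the total effect — an identity the test
suite checks by independent simulation. These estimands use only
single-world counterfactuals: no intervention on the mediator and no
cross-world independence assumption is needed. Identification requires
randomised treatment, conditional independence of `M_t` from `X^Y`
given the observed past and `X^M`, and of `Y_t` from `X^M` given the
observed past and `X^Y`.

## The two data-generating mechanisms

### Cross-lagged linear mixed model

```
E[M_it | ·] = (β0 + b0i) + βX Xi + β_lag_m M_i,t−1 + β_lag_y Y_i,t−1
E[Y_it | ·] = (γ0 + g0i) + γX Xi + (γM + gMi) M_it
              + (γ_lag_m + g_lag_m,i) M_i,t−1 + γ_lag_y Y_i,t−1
```

with `(b0, g0, gM, g_lag_m) ~ MVN(0, Φ)` per subject and Gaussian
residuals. Wave-1 equations carry no lagged terms. Identifiability of
the separable effects depends on the zero pattern of `Φ`
(`check_identifiability`): diagonal → non-parametric via the
mediational g-formula; block-diagonal (covariance within the mediator
or outcome random-effect block only) → parametric, because
integrating the random effects uses their Gaussian law; any
cross-block covariance → not identified (both exposure components
then affect one latent-connected, *recanting* district).

Closed-form truths are implemented for waves 1–2 by path tracing. The
wave-2 direct effect multiplies `γX` by
`1 + β_lag_y·γM + γ_lag_y` (the paths `X^Y→Y2`, `X^Y→Y1→M2→Y2`,
`X^Y→Y1→Y2`). The wave-2 indirect effect contains the square of the
random slope `(γM + gM)²`, whose expectation is `γM² + Var(gM)` — the
second-moment correction matters whenever `Var(gM) > 0` (for the
default design it moves the wave-2 SIE from 0.2032 to 0.2582). Beyond
wave 2 the number of open paths and random-coefficient products grows
quickly, so `mixed_effects_asymptotic` evaluates the truth by forward
Monte-Carlo simulation of the generating recursion with the exposure
split into its components, averaging the conditional outcome mean
(10⁶ draws by default, Monte-Carlo SEs reported, common random
numbers across the three component interventions).

### Parallel-process latent growth model

Measurements load on latent intercept/slope pairs,
`M_it = η0M,i + λ_t η1M,i + ε`, `Y_it = η0Y,i + λ_t η1Y,i + ε`, with
time coding fixed at `λ_t = t − 1` (so wave 1 identifies the latent
intercepts). The structural layer regresses each latent on `X`, and
the outcome slope additionally on the mediator latents:
`η1Y = γ10 + γ11 X + γ12 η0M + γ13 η1M + ζ`. Exact effects follow by
path tracing:

```
SDE_t = (γ01 + γ11 λ_t)(x − x')
SIE_t = λ_t (β01 γ12 + β11 γ13)(x − x')
```

The latent factors are never observed, so identification is always
parametric here.

## Study designs (simulator defaults)

The replication designs use `T = 5` waves and the coefficient sets

| mixed      |      | latent growth |      |
|------------|------|---------------|------|
| β0         | 1.3  | β00           | 0.21 |
| βX         | 0.5  | β01           | 0.16 |
| β_lag_m    | 0.27 | β10           | 0.70 |
| β_lag_y    | 0.11 | β11           | 0.47 |
| γ0         | 0.45 | γ00           | 0.30 |
| γX         | 0.7  | γ01           | 0.14 |
| γM         | 0.2  | γ10           | 0.59 |
| γ_lag_m    | 0.08 | γ11           | 0.27 |
| γ_lag_y    | 0.34 | γ12           | 0.44 |
|            |      | γ13           | 0.19 |

with identity `Φ` (uncorrelated unit-variance random effects),
standard-Normal latent disturbances, and exposure randomised with
probability 0.5. The residual and measurement error standard
deviations default to 1.0; these scales are free parameters of the
designs and are configurable. The unobserved-confounder variants use
`u_effect = 1.0, u_sd = 1.0` by default; these magnitudes are design
choices, so the confounding experiments are interpreted directionally
(sign and ordering of biases), not by magnitude.

What the generators deliberately do not emulate: unbalanced or
censored designs, time-varying exposures, non-Gaussian latent
disturbances, and covariate-driven confounding of the exposure
(treatment is always randomised). Passing tests therefore demonstrate
correctness of the estimators under the stated mechanisms, not
robustness to real-data features outside them.

## Estimation

### g-formula Monte-Carlo engine

Following the three-step algorithm: (1) fit conditional models for
`f(M_t | X, M̄_{t−1}, Ȳ_{t−1})` and `f(Y_t | X, M̄_t, Ȳ_{t−1})`;
(2) simulate `S ≥ 10,000` subjects forward with the mediator models
evaluated at `x_m` and the outcome models at `x_y`, sampling
intermediate mediators and outcomes (Gaussian draws use the residual
root-MSE scale; Gamma draws use the fitted dispersion); (3) average
the conditional outcome mean at each wave over simulated subjects.
The three interventional means needed for SDE and SIE share one
random-number stream (common random numbers), which reduces contrast
variance and makes SDE + SIE equal the total-effect contrast exactly.
Uncertainty comes from a non-parametric cluster bootstrap: subjects
resampled with replacement, the backend refitted per resample,
percentile intervals over `B` replicates (`B = 500` default; `B = 0`
skips the bootstrap for replication studies that only need means).

### Backends

- **glm** — pooled-over-waves (default) or per-wave GLMs
  (Gaussian-identity, binomial-logit, Gamma-log). Pooling shares one
  coefficient vector across waves, matching the lag-indexed
  parameterisation of the mechanisms; wave-1 lag columns are
  zero-filled, which leaves the wave-1 likelihood untouched while
  permitting a single design matrix.
- **mixed** — `statsmodels MixedLM`, random intercept in the mediator
  equation; random intercept plus slopes on `M_t` and `M_{t−1}`
  (diagonal covariance by default, `block` optional) in the outcome
  equation. Cross-validated against lme4 in the test suite. The
  g-formula draws subject-level random effects from the estimated
  covariance. Lagged outcomes are formally correlated with the random
  effects, which ordinary mixed-model ML ignores; replicated fits at
  the study design show no detectable bias at these parameter values
  (pilot means within one SE of truth at n = 2000, K = 8).
- **lgm** — Gaussian maximum likelihood on the model-implied mean and
  covariance of the stacked `(M_1..M_T, Y_1..Y_T)` given `X`, fixed
  loadings, L-BFGS-B from method-of-moments starting values
  (per-subject OLS factor scores), log-parameterised scales bounded
  in `[1e−3, 1e3]`, gradient tolerance 1e−8, up to 5 jittered
  restarts. Group sufficient statistics make one fit ~0.2 s at any n.

### Misspecification modes

- *moderate, mixed*: drop `Y_{t−1}` from the mediator model
  (`mediator_lag_y=False`).
- *moderate, latent growth*: drop `η0M` from the `η1Y` equation. A
  subtlety: deleting the path while forcing the corresponding latent
  covariance to zero would push the unexplained
  `cov(η0M, η1Y) = γ12·Var(η0M)` into the fitted `γ13` (inflating it
  to ≈0.34 under the study design), which is not how the classical
  omitted-variable analysis — or the replication targets — behave.
  The package therefore deletes the *structural* path but leaves the
  disturbance covariance between `η0M` and `ζ_η1Y` free, keeping the
  covariance structure saturated; the remaining coefficients then
  converge exactly to their omitted-variable regression limits
  (`γ11 → γ11 + γ12 β01 = 0.3404`, `γ13 → 0.19`), and effects are
  computed from the analyst's structural equations, which exclude the
  deleted path.
- *severe*: fit the other mechanism's model class altogether
  (mixed-mechanism panels as latent growth models and vice versa).
- *assumption violation*: simulate with the unobserved confounder.
  For the mixed mechanism the violation experiment retains the
  moderately misspecified mediator model, which is the combination
  that reproduces the documented pattern (early-wave indirect-effect
  overestimation from the confounder, progressive late-wave
  attenuation); the latent-growth violation experiment fits the
  correctly specified model, whose point estimates stay near-unbiased
  while their sampling variance inflates.

## Replication harness

`run_scenario` simulates `K` independent panels (replicate seeds
derived from `(scenario seed, k)` so parallel and serial execution
agree bit for bit), fits the mapped backend, estimates effects, and
reports per wave: relative bias `Σ(θ̂_k − θ)/(Kθ)`, RMSE
`sqrt(Σ(θ̂_k − θ)²/K)`, and the coverage of nominal-95% bootstrap
intervals. Per-replicate failures are tolerated up to 5%. Truths come
from the closed forms (latent growth) or the asymptotic oracle
(mixed), computed once per scenario.

## Numerical choices and problem sizes

- Random-effect covariances are factored by eigendecomposition with
  eigenvalues clipped at zero, so degenerate (zero-variance) designs
  simulate exactly without jitter.
- The acceptance runs use 10⁶ oracle draws (Monte-Carlo SE ≈ 1e−4 on
  the wave-2 SDE), K = 100 replicates of n = 1000 for the
  misspecification means, and K = 100 × B = 120 for the coverage
  experiment at n = 1000 — sizes at which every comparison's
  Monte-Carlo error is well inside its acceptance band. Unit tests
  use 10⁴-draw oracles.
- `proportion_mediated = SIE/(SDE + SIE)` is reported as NaN with a
  warning when the total effect is zero.

## Known limitations

- Mixed-mechanism closed forms stop at wave 2; later waves rely on
  the Monte-Carlo oracle (exact closed forms grow combinatorially).
- The mixed backend's ML treats lagged outcomes as exogenous given
  the random effects (see above); at strong autoregression and large
  random-effect variances this could bias estimates.
- The g-formula engine does not average over baseline covariate
  distributions; covariate-bearing fitted models are rejected rather
  than silently marginalised.
- Exposures with more than two levels, multiple mediator processes,
  unbalanced panels and time-varying treatments are out of scope.
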