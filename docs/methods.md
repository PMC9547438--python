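# Methods

## Model

For subject i let `y_ci` be the log-transformed PK parameter and
`y_bi ∈ {0,1}` the binary immunogenicity outcome (ADA positive/negative, or
high vs. low/zero titer subgroup — the package treats the two readings
interchangeably; no titer classification is performed). The joint density
is factorized into a binary margin and a conditional continuous outcome:

```
probit(E[y_bi | x_bi]) = x_bi' β_b                       (probit margin)
y_ci | y_bi = x_ci' β_c + τ·(y_bi − Φ(x_bi' β_b)) + ε_ci,  ε ~ N(0, σ_c²)
```

The joint log-likelihood is the sum of the probit log-likelihood of
`y_b` and the normal log-density of `y_c` at the conditional mean. Writing
`η_b = x_b' β_b`, each subject contributes

```
−½ log(2π σ_c²) − (y_c − x_c'β_c − τ(y_b − Φ(η_b)))² / (2σ_c²)
+ y_b log Φ(η_b) + (1 − y_b) log(1 − Φ(η_b)).
```

Key properties, each verified by tests:

- **Marginal interpretation.** `E[y_b − Φ(η_b)] = 0`, so `x_c'β_c` is the
  marginal mean of `y_c`: the treatment component of β_c is the log-GMR.
- **Separability at τ = 0.** The likelihood splits exactly into an OLS
  normal likelihood and a probit likelihood; the constrained fit
  (`tau_fixed=0`) reproduces their sum to 1e-6.
- **Mixture structure.** Marginalizing the binary outcome makes
  `y_c | x` a two-component normal mixture with variance
  `τ²Φ(η_b)(1−Φ(η_b)) + σ_c²` and model-implied outcome correlation
  `sign(τ)/sqrt(1 + σ_c²/(τ² Φ(η_b)(1−Φ(η_b))))`.
- **Scope of the efficiency gain.** The model outperforms ANOVA only when
  the two equations use different covariate sets; the treatment indicator
  must appear in the continuous equation only. `ModelSpec` enforces the
  latter and warns when the term sets coincide.

The probit link is the only supported binary link (the conditional-mean
and variance formulas above are probit-specific). No latent-variable
(shared random effect) joint model and no Bayesian estimation are provided.

## Estimation and inference

The negative log-likelihood is minimized by BFGS on the unconstrained
parameterization `(β_b, β_c, τ, log σ_c)` with analytic gradients.
Starting values are method-of-moments: β_b from a probit fit (in-module
Fisher scoring), β_c and σ_c from least squares, τ from the covariance of
the two residual series divided by the binary residual variance. On
non-convergence the start is jittered by ±20% (deterministically seeded)
up to three times; a fit that still fails is returned with
`converged=False` rather than raising, so Monte-Carlo batches never abort.
Fitted probabilities are clipped to `[1e-12, 1 − 1e-12]` inside logarithms.
A BFGS stop flagged "precision loss" with a gradient max-norm below 1e-5
is treated as converged — at trial-size n this is an optimum reported
over-cautiously, not a failure.

The covariance of the estimates is the inverse observed information,
obtained by central differences of the analytic gradient with step
`eps^(1/3) · max(1, |θ_j|)`. Convergence additionally requires this matrix
to be positive definite.

**Finite-sample calibration.** The raw ML information carries no
residual-degrees-of-freedom correction, so equivalence tests built on it
are slightly liberal at realistic trial sizes (measured ≈ 5.4% type-I at
the margin boundary with n = 200). The package therefore scales the
covariance by `n/(n − p)`, where p counts the conditional-mean parameters
of the continuous equation (β_c plus τ), and uses a Student-t reference
with `n − p` degrees of freedom for Wald intervals — the exact analogue of
the correction that makes the OLS comparator's intervals exact. The
comparators use the classical t(n − p) OLS inference throughout, so any
residual z-vs-t sensitivity is visible in the paired simulations.

## Equivalence rule

`gmr_interval` exponentiates `b ± q·SE(b)`; `assess_equivalence` passes
when the CI lies inside the margins, inclusively at both ends ("fall
within" is read inclusively; under continuous sampling the boundary is a
measure-zero event, so simulated rates are unaffected). The default 90%
two-sided CI at margins [0.80, 1.25] is operationally identical to TOST at
α = 5%; no separate TOST p-values are computed.

## Synthetic data generator

`simulate_study` emulates a two-arm (1:1) parallel single-dose design.
Per arm, triples (ADA latent, log-PK latent, covariate) are drawn from a
trivariate standard normal via the Cholesky factor of a latent correlation
matrix in that fixed order; the ADA latent is dichotomized at its
(1−p)-quantile. Design choices:

- **Correlation targets are realized, not latent.** The configured
  `r_pk_ada` and `r_cov_ada` are target point-biserial correlations of the
  *binary* ADA variable with log-PK and the covariate; latent correlations
  are obtained by inverting the attenuation map `δ = ρ·h/√(p(1−p))`
  per arm (h = normal density at the cut). `targets_are_latent=True`
  switches to the latent reading for sensitivity analysis. Infeasible
  targets (|ρ| ≥ 1 or a non-PD matrix) are rejected at config
  construction, never mid-stream.
- log-PK = anchor + ln(GMR)·1[arm = T] + σ·Z with σ = √(ln(1+CV²));
  the reference anchor is ln(5000), an arbitrary but realistic AUC-like
  magnitude — all inference depends only on arm differences.
- The covariate is standard normal, correlated with ADA but independent
  of log-PK (it belongs in the binary equation only).
- A negative PK–ADA correlation means ADA-positive subjects have lower
  exposure, matching the clinical phenomenon the model targets.
- Equal σ and equal correlation targets in both arms; ADA rates may
  differ by arm. Odd totals allocate the extra subject to R.
- Replicate r of a scenario uses `numpy.random.default_rng(seed + r)`, so
  every result is bit-reproducible at fixed library versions and all
  methods can be paired on identical data.

What the generator does **not** emulate: ADA onset dynamics and titer
trajectories (ADA is cross-sectional), concentration–time curves (one PK
parameter per subject), crossover designs, heavier-tailed or skewed
log-PK, missing data, or arm-specific variances. Passing tests therefore
demonstrate correct behavior under a dichotomized-Gaussian world, not
robustness to every feature of real trial data. Note also that the
factorization model is a *working* model for this generator (the true
conditional mean of a dichotomized Gaussian is not exactly of the
`τ·(y_b − Φ)` form), which is precisely the robustness setting the
simulations are meant to probe; the remaining ≈2% understatement of the
Wald SE observed at n = 200 is the footprint of that mismatch.

## Operating characteristics

`run_oc`/`run_grid` per replicate: simulate → fit → 90% GMR CI →
margin decision. Pass rate is power (true GMR inside the margins) or
type-I error (true GMR = 0.80 on the boundary). Within a scenario all
methods analyze the same data (common random numbers), which sharpens the
dominance comparisons; non-converged replicates count as failures
(conservative, mirroring regulatory practice) with the convergence rate
reported separately. The default factorization layout matches the
simulation design: treatment in the PK equation, the baseline covariate in
the ADA equation.

`analytic_anova_sample_size` computes the exact TOST power for a 1:1
parallel design from noncentral-t tail probabilities (pooled SD on n − 2
df) and returns the smallest even total reaching the target; at GMR 0.95,
CV 0.4, α 5%, 80% power it returns 130. `sample_size_search` does the same
by simulation for any method: bracketed bisection on the even-n grid with
common random numbers, a ±4 local scan to undo bisection noise, then a
higher-replicate confirmation at the returned n.

Scenario grids mirroring the simulation study are provided:
36 power scenarios (GMR 0.95, CV 0.4, n 130; reference ADA rate 20/40/60%
with test-arm excess 0/5/10 points; PK-ADA correlation −0.3/−0.5;
covariate-ADA 0.1/0.3), 6 type-I scenarios (GMR 0.80, CV 0.4, n 200,
equal rates, covariate-ADA 0.1), and 12 sample-size scenarios
(CV 0.3–0.6, rate 50%, PK-ADA −0.3/−0.5/−0.6).

## Monte-Carlo sizes and tolerances

Library defaults are 5,000 replicates per cell. The test suite and the
acceptance script run the type-I scenarios at 2,000 replicates and the
reduced qualitative grids at 600–2,000 replicates — the package's
desk-scale defaults, with the binomial MC standard error always reported
and all stochastic assertions stated in MC-SE units (3 SEs for rate
comparisons, 2 combined SEs for paired dominance). Measured calibration at
these settings: boundary type-I ≈ 5.0–5.2% per scenario, ANOVA power at
n = 130 ≈ 80%, Wald-SE-to-empirical-SD ratio ≈ 0.98 at n = 200.

## Data handling

PK values live on the natural-log scale internally; raw-scale values are
log-transformed at the CSV boundary (strictly positive required).
Records with missing values in modeled columns are dropped complete-case
with a logged count. Binary ADA must be coded 0/1; arms are the literals
`T` and `R`. CSV round-trips are bit-exact (`float_precision="round_trip"`
on read).
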