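# Methods

This document defines the statistical models fitted by `mixls`, the
estimation algorithms, and the numerical design choices, in enough detail to
reproduce the implementation.

## 1. Stage 1: mixed-effects location-scale models

### 1.1 MELS (random intercept + random scale)

For subject *i* = 1…N at occasion *j* = 1…n_i:

    y_ij = x_ij' β + υ_i + ε_ij

- **Location effect** υ_i: between-subject (BS) deviation with a log-linear
  variance model.  Writing the BS standard deviation as
  σ_υ(u_i) = exp(u_i' α / 2) for subject-level covariates u_i,

      υ_i = σ_υ(u_i) · θ1_i,        θ1_i ~ N(0, 1).

- **Within-subject (WS) variance** with covariates w_ij, an optional
  association with the subject's own location effect, and a random scale
  effect θ2_i ~ N(0, 1) independent of θ1:

      ε_ij ~ N(0, σ²_ij),
      log σ²_ij = w_ij' τ  +  τ_l υ_i  (+ τ_q υ_i²)  +  σ_ω θ2_i.

  The association structure is selected by `ncov`:

  | `ncov` | WS-variance association terms |
  |--------|-------------------------------|
  | 0      | none                          |
  | 1      | linear: τ_l υ_i               |
  | 2      | linear + quadratic: τ_l υ_i + τ_q υ_i² |

  `random_scale=False` removes σ_ω θ2 (one integration dimension instead of
  two).

Internal parameter vector (in order): β, α, τ, then τ_l (and τ_q) when
`ncov ≥ 1`, then σ_ω.  σ_ω is estimated on the standard-deviation scale with
a positivity floor of 1e−3 (projected-gradient handling at the bound); all
variance intercepts/coefficients are on the log scale, so the parameter
space is otherwise unconstrained.

### 1.2 MEMLS (multiple random location effects + random scale)

With a random-effect design z_ij (intercept plus up to two random slopes):

    y_ij = x_ij' β + z_ij' υ_i + ε_ij,     υ_i = S s_i,   s_i ~ N(0, I),

where S is the lower-triangular Cholesky factor of the location-effect
covariance Σ_υ = S S'.  Internally S is stored row-major with the diagonal
on the log scale, so every real parameter vector maps to a valid
(positive-definite) Σ_υ.  The WS variance model is

    log σ²_ij = w_ij' τ  +  τ_υ' s_i  +  σ_ω θ2_i,

with the location association τ_υ expressed in the **standardized** basis
s_i (`ncov ∈ {0, 1}`).  Reported covariance tables are transformed back to
Σ_υ with delta-method standard errors.  The total integration dimension
(location effects + random scale) is capped at 3.

### 1.3 Marginal likelihood and quadrature

Conditional on the standardized effects θ the data are Gaussian, so the
marginal log-likelihood is a sum over subjects of log ∫ f(y_i | θ) φ(θ) dθ,
approximated by tensor-product Gauss–Hermite quadrature over the
standardized effects.

**Adaptive (moment-based) quadrature.**  Each subject's node set is
recentred and rescaled at the posterior mean and covariance of θ (computed
as normalized quadrature moments), and this adaption is iterated to a fixed
point (tolerance 1e−9 on the moments).  Moment-based adaption — rather than
mode/curvature-based — stays smooth in the parameters and degrades
gracefully for multimodal posteriors (the grid straddles the modes).

Three properties discovered during development shape the implementation:

1. **Cold-started, deterministic adaption inside the optimizer.**  The fixed
   point is always reached from the prior-centred start, never warm-started
   from whatever grid the previous objective evaluation left behind.
   Warm-starting is faster but history-dependent: in some regions the
   adaption map has several self-consistent placements, and a warm start can
   converge onto a spurious one, feeding the line search values from
   different attractors (observed discrepancies of tens of log-likelihood
   units at the same parameter point).  Cold starts make the fitting
   objective a deterministic function of the parameters.
2. **Divergence detection.**  If the moment iteration is still moving by
   more than 1e−3 after its cycle budget, the candidate parameter point is
   treated as invalid (objective −∞) rather than returning a meaningless
   quadrature value; the line search then backtracks.  This typically
   triggers for extreme location-association parameters, where the adapted
   grid chases the integrand into the tail.
3. **At least 7 points per dimension.**  Below 7 adaptive points the
   quadrature error becomes sensitive to grid placement, which biases the
   analytic score relative to the objective and can stall the optimizer (at
   5 points we measured frozen-grid scores disagreeing with true directional
   derivatives by factors of ~5).  A `UserWarning` is emitted for adaptive
   fits requested with fewer than 7 points.  Defaults: 11 points per
   dimension for 1–2 dimensions, 7 for 3 dimensions.

Non-adaptive (prior-centred) grids are supported for oracle comparisons and
testing, but converge slowly when the data are informative; they are not
recommended for estimation.

### 1.4 Optimization

Each model is fitted as a chain of nested submodels, each warm-starting the
next:

1. the standard multilevel model (mean model, BS-variance covariates,
   WS-variance intercept) — started from OLS coefficients and a
   moment-based BS/WS variance decomposition;
2. \+ WS-variance covariates and the location association (new parameters
   start at 0);
3. \+ the random scale effect (σ_ω starts at 0.1).

The maximizer is Newton–Raphson with Levenberg–Marquardt damping:

- the gradient is the **analytic score** of the quadrature objective,
  treating the freshly adapted nodes as fixed (the neglected
  adaption-movement term is second-order small at quadrature convergence);
- the Hessian is a central finite difference of the score evaluated on the
  most recently adapted grid (cheap; the damping absorbs the approximation);
- the damping parameter λ persists across iterations: failed line searches
  escalate it (bending the step toward short gradient ascent), successful
  full steps reset it;
- a backtracking line search with an infinity-norm trust region (step cap
  2.0) guards every step; a plain gradient-ascent line search is the last
  resort;
- convergence is declared on (a) a first-order test — projected gradient
  below 1e−8 · max(1, |LL|) — or (b) small step and small LL change with
  either an undamped step or a projected gradient below 1e−3 · max(1, |LL|),
  or (c) three consecutive stalled iterations with a small projected
  gradient (a weakly identified flat ridge, where steps drift along the
  non-identified direction without shrinking).

**Quadrature escalation.**  A grid with few points per dimension can admit
several self-consistent adapted placements in sensitive regions, making the
approximate objective discontinuous there; rarely, the optimizer lands
exactly on such an artifact and no improving step exists despite a large
gradient.  When a submodel fit stalls, it is automatically retried from the
current iterate with 4 more quadrature points per dimension (up to twice,
e.g. 7 → 11 → 15), with a `UserWarning`.  Refining the grid removes the
multiplicity; in testing this resolved every observed stall.

Standard errors come from the inverse negated finite-difference Hessian of
the analytic score at the MLE; if that information matrix is not positive
definite (boundary solutions), a pseudo-inverse is used with a warning.
Information criteria are reported on the log-likelihood scale:
AIC = LL − p and BIC = LL − ½ p ln N (N = subjects), so *larger is better*.

### 1.5 Empirical-Bayes estimates

Posterior means and covariances of the standardized effects
(θ1[, θ2] for MELS; s_1, s_2[, θ2] for MEMLS) are computed as normalized
quadrature moments on the final adapted grid and exposed per subject
(`Stage1Results.empirical_bayes()`), including the full posterior
covariance needed for plausible-value sampling.

## 2. Stage 2: plausible-value regressions

Point estimates of latent effects (EB means) are shrunken and ignore
posterior uncertainty; regressing an outcome on them directly biases
coefficients and understates standard errors.  Instead:

1. **Plausible values.**  For imputation m = 1…M (default M = 500), draw
   θ_i^(m) ~ N(EB mean_i, EB covariance_i) for every subject.  Draws use
   `numpy.random.SeedSequence(seed)` spawned into per-imputation
   substreams, so the first imputations of a run agree across different M
   and runs are reproducible; the user seed must lie in 1…65000.
2. **Per-imputation fit.**  The subject-level design is built from observed
   regressors, the drawn location effect(s) and scale effect, and an
   interaction grammar (effect × regressor and location × scale products,
   each suppressible).  The outcome model is
   - *continuous*: linear regression (ML residual variance reported as an
     extra `Residual_Variance` row),
   - *dichotomous*: logistic regression (non-0/1 codings are auto-recoded),
   - *ordinal*: proportional-odds model with increasing thresholds
     (`Threshold_k` rows, delta-method covariance).
3. **Pooling (Rubin's rules).**  Estimates average across imputations; the
   total variance is T = W̄ + (1 + 1/M) B with W̄ the mean within-imputation
   variance and B the between-imputation variance.  The average
   log-likelihood and its across-imputation SD are reported.

## 3. Simulation and validation tools

`mixls.simulate` generates data from the exact generative models above
(`SimulationConfig`, `simulate_stage1`, `simulate_two_stage`), returning the
latent per-subject truth for validation, and `recovery_experiment` runs
replicated simulate→fit studies reporting bias, Monte-Carlo SEs, RMSE and
95% Wald coverage per parameter.  These back the property-based acceptance
tests: quadrature vs dense-grid oracles, closed-form multivariate-normal
special cases, conjugate-posterior EB checks, exact Rubin pooling, and
parameter-recovery calibration.

## 4. Limitations

- Integration is capped at 3 dimensions (≤ 2 random location effects plus a
  random scale); more random slopes would need sparse grids or Monte-Carlo
  integration.
- Non-adaptive grids are oracles for weakly informative data only; with
  long series their prior-scale placement converges very slowly.
- The submodel chain's likelihood monotonicity holds to optimizer stopping
  precision (~1e−3), not exactly.
- Stage 2 assumes complete subject-level data (no missing-outcome
  imputation) and one outcome per run.
- Ordinal stage-2 models rely on BFGS in statsmodels and may need more
  iterations for many categories.
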