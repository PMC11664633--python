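# Methods

This note records the model, the algorithms, the numerical choices and the
open design decisions behind `tvcox`, in enough detail that a maintainer
can reconstruct why the code is the way it is.

## Model and likelihood

Right-censored survival data: n subjects with covariates z_i ∈ R^p,
follow-up time t_i > 0, event indicator δ_i ∈ {0,1}, optional stratum
label. The hazard is

    λ(t | z_i) = λ_0s(t) · exp(z_i' β(t)),

with a stratum-specific, unspecified baseline λ_0s and a coefficient
function β(t) shared across strata. Each coordinate is spanned by a common
B-spline basis, β_j(t) = Σ_k θ_jk B_k(t), so the estimand is the p × K
matrix θ. Left truncation, interval censoring, time-varying covariate
*values* and recurrent events are out of scope; the model covers
time-varying covariate *effects* on right-censored data only.

Estimation maximizes the log-partial likelihood with the **Breslow**
approximation for ties: for each stratum and each distinct event time t_m
with tie set D_m (d_m events) and risk set R_m = {l : t_l ≥ t_m},

    ℓ(θ) = Σ_m [ Σ_{i∈D_m} η_i(t_m) − d_m log Σ_{l∈R_m} exp(η_l(t_m)) ],

η_i(t) = z_i'β(t). Each event-time term is a log of a ratio bounded by 1,
so ℓ ≤ 0, and when all d_m = 1 the expression is the exact untied partial
likelihood. Efron's tie correction is deliberately not implemented.

Conventions fixed once and relied on everywhere:

* vec(θ) is **covariate-major** (all K coefficients of covariate 1, then
  covariate 2, …) — `theta.ravel()` for θ of shape (p, K). The Hessian
  layout, the block-diagonal penalty and the Wald contrasts all assume it.
* A subject censored at exactly an event time is **in** that risk set
  (events precede censorings at tied times).
* Basis knots are placed on the distinct event times **pooled across
  strata**, because β(t) is shared across strata.
* Covariates are used as supplied; there is no internal standardization.

## Basis

Clamped B-splines via `scipy.interpolate.BSpline`: degree 3 and K = 8 by
default (the middle of the 5–10 working range; degree 2 is supported
because the first-derivative smoothing penalty is defined for it).
Interior knots sit at equally spaced quantiles of the *distinct* event
times — quantile placement balances the number of events per knot
interval, which keeps the per-interval information roughly constant; a
uniform rule is available. Boundary knots at the smallest and largest
distinct event time with multiplicity degree+1. Evaluation outside the
boundary clamps to it (constant extrapolation of β), which is needed when
predicting at censoring times beyond the last event; a strict mode raises
instead. Quantile knots that collide on heavily tied grids are nudged into
the strict interior by one ulp rather than rejected.

## Gradient, Hessian, and the Kronecker structure

With x_i(t) = z_i ⊗ B(t) (so η_i(t) = x_i(t)'vec(θ)), the gradient and
Hessian of ℓ are accumulated event time by event time:

    g_m = Σ_{i∈D_m} x_i − d_m x̄_m,
    H_m = −d_m ( Σ_l w_l x_l x_l' − x̄_m x̄_m' ),    x̄_m = Σ_l w_l x_l,

where w_l are softmax weights of η_l(t_m) over R_m. Because
x_l x_l' = (z_l z_l') ⊗ (B B'), only the weighted first and second moments
of z over the risk set (a p-vector and a p × p matrix) and the K-vector
B(t_m) are formed per event time; the n × pK expanded design never exists.
Subjects are pre-sorted by descending time per stratum so every risk set
is a prefix of the sorted arrays. Each H_m is −d_m times a weighted
covariance, hence ℓ is concave in vec(θ) everywhere — the foundation for
the monotone-ascent guarantee below. Every risk-set sum is computed with
log-sum-exp shifting, so extreme linear predictors (ill-conditioned binary
covariates, line-search overshoots) degrade gracefully.

The test suite pins this machinery to an independent dense Newton solver
built on the explicitly expanded counting-process design (tests/_oracles.py)
to 1e-6 per coefficient, and to `lifelines` for the K=1, degree-0 reduction
to the standard Cox model.

## Penalties

Both penalties are λ Σ_j θ_j' S θ_j with one K × K PSD matrix S and a
single λ shared by all covariates (per-covariate λ is a deliberate
non-feature: the tuning surface stays one-dimensional; the matrix plumbing
would extend to a vector of λs without structural change).

* P-spline: S = D_d'D_d with D_d the d-th order difference matrix.
  Default d = 2 (standard in the P-spline literature). The λ → ∞ limit
  forces θ_j into the null space of S: for d = 1 exactly the constant
  coefficient vectors, giving a constant effect equal to the standard Cox
  coefficient; for d = 2 coefficient sequences linear in the basis *index*,
  which on non-uniform quantile knots is close to but not exactly linear
  in *t*. The constant-limit checks therefore run at d = 1, where the
  limit is exact; both orders are kept and documented rather than
  collapsed.
* Smoothing spline: S_kl = ∫ B_k^(r) B_l^(r) dt, r = 2 for cubic bases
  (λ → ∞ limit: straight-line effects) and r = 1 for quadratic (limit:
  constant effects). The integrand is piecewise polynomial of degree
  2(degree − r), so Gauss–Legendre with degree − r + 2 nodes per knot
  interval integrates it exactly; the matrix is verified against adaptive
  quadrature to 1e-9.

The penalized objective is ℓ(θ) − λ Σ_j θ_j'Sθ_j; its Hessian subtracts
2λ·blockdiag(S,…,S). Concavity is preserved for every λ ≥ 0.

## Optimizer

Damped ("proximal") Newton with backtracking:

1. Solve (−H + τI) δ = g by Cholesky. τ starts at 0; on a factorization
   failure or a non-ascent direction it is raised to
   max(1e-8, 1e-4·max diag(−H)) and escalated ×10, capped at 1e12, after
   which the fit aborts with a conditioning diagnostic recommending a
   penalized fit or a smaller K.
2. Backtrack from step 1 by halving under the Armijo condition
   f(θ + sδ) ≥ f(θ) + 1e-4·s·g'δ (at most 50 halvings). A stalled line
   search with max|g| < 1e-5 is treated as converged-with-warning;
   otherwise τ escalates and the iteration retries.
3. Stop when the relative objective change is below 1e-9 (default) or at
   200 iterations; the `converged` flag and final gradient max-norm are
   reported honestly, never assumed.

θ starts at 0 (the null model), there is no randomness anywhere in
fitting, and accepted steps by construction never decrease the objective —
the iteration trace is asserted non-decreasing on every fit in the test
suite. λ paths are fitted in descending order with warm starts, so the
heavily penalized (nearly quadratic) end of the path stabilizes the start
of the flexible end.

The negative penalized Hessian at θ̂ and its inverse are stored on the
fitted model and anchor *all* variance statements. For penalized fits this
is the Bayesian-style (non-sandwich) variance; the coverage simulation in
the test suite documents its behavior on unpenalized fits (95% pointwise
band covers at the nominal rate within MC error). A sandwich alternative
was considered and not implemented: refitting without penalty is the
supported route to frequentist unpenalized variances.

## Tuning

Information criteria use the standard penalized-likelihood trace
constructions, with H the unpenalized and P the penalized negative Hessian
at θ̂(λ) and J the outer product of per-event-time score contributions:

    mAIC = −2ℓ + 2 tr(P⁻¹H),  TIC = −2ℓ + 2 tr(P⁻¹HP⁻¹H),  GIC = −2ℓ + 2 tr(P⁻¹J),

effective df = tr(P⁻¹H). These are pinned as *the* definitions for this
package; the anchors are exact at λ = 0 (df = pK, mAIC = classical AIC,
mAIC = TIC) and the order-1 P-spline limit df → p. Criterion ties resolve
to the larger λ (prefer the smoother model).

Cross-validation scores λ by the cross-validated partial likelihood in the
Verweij–van Houwelingen form, Σ_folds ℓ_full(θ̂_train) − ℓ_train(θ̂_train),
rather than the naive held-out partial likelihood — small test folds have
degenerate risk sets, while the full-minus-train difference is always well
defined. Folds come from a seeded shuffle stratified on event indicator
and stratum; an assignment leaving any training split without an event in
some stratum is redrawn (up to 20 attempts). Results are deterministic
given the seed; fold fits may be evaluated in any order (nothing is
accumulated across folds except the final sums), so a parallel map is a
safe drop-in.

## Inference

Wald tests per covariate j with V_j the covariate's K × K block of the
stored inverse information: proportional hazards (C θ_j = 0 with C the
adjacent-difference contrast, χ² with K−1 df — invariant to which basis of
the constants' complement is used, which the suite asserts), zero effect
(θ_j = 0, K df), and pointwise β_j(t) = 0 (1 df per grid time, no
multiplicity adjustment by default with an optional Bonferroni flag, and
the default grid is the distinct event times in the CLI). Singular
contrast covariances fall back to a pseudo-inverse with rank-adjusted df
and are flagged. Pointwise confidence bands use the same V_j, so the
pointwise test statistic and the band are exactly consistent.

## Prediction

Breslow baseline increments dΛ_0s(t_m) = d_m / Σ_{l∈R_m} exp(η̂_l(t_m)) per
stratum; at θ̂ = 0 this is exactly the (tied) Nelson–Aalen estimator,
which the suite asserts. Survival prediction composes the increments with
exp(z'β̂(t_m)); β̂ beyond the last event time uses the clamped (boundary)
value, flagged in the curve export. Curve exports are tidy long tables
(log-HR default, HR behind a flag) written with 17 significant digits so
CSV round-trips are bit-identical.

## Simulator

Event times are drawn by inverting the subject-specific cumulative hazard
Λ_i(t) = m_s ∫_0^t exp(z_i'β(u)) dΛ_0(u) on a 2000-cell grid over
[0, t_horizon] (baseline increments in closed form per family —
exponential, Weibull, piecewise — times exp(η) at cell midpoints; an
Exp(1) draw is mapped back by linear interpolation). The grid is the only
approximation: halving the step moves the mean event time by < 0.1% (a
suite assertion). Horizon defaults to the time where the baseline
cumulative hazard reaches 10 (baseline survival ≈ 4.5e-5), so implicit
truncation is negligible unless a horizon is set on purpose. Censoring is
independent (uniform / exponential / administrative); rounding to a fixed
number of decimals manufactures ties, and a time that rounds to zero is
redrawn. An event fraction outside (0.02, 0.98) warns but proceeds —
designs without censoring are legitimate.

What the generator emulates: the data schema, independent right censoring,
tied times from coarse recording, stratified baselines, and effect shapes
(constant, linear, sine, decaying exp). What it does not: dependent
censoring, covariate measurement error, delayed entry, non-loglinear
covariate effects, and real-registry messiness (missingness, coding
drift). Passing tests therefore demonstrate correctness of the estimator
under the model's own assumptions, not robustness to their violation.

The packaged example (`make_example_data`) is n = 2000, two standard-normal
covariates, β₁(t) = 1 and β₂(t) = sin(πt/3), unit exponential baseline,
horizon 3, uniform(0, 6) censoring — calibrated once to ≈ 25% censoring.
One covariate satisfies proportional hazards, the other violates it
detectably: the smallest design that exercises both branches of the PH
test. The decaying scenario used in the recovery checks (β(t) = 1.5·e^
{−0.35t}, horizon 8) mirrors the qualitative trajectory of a
late-vs-early-stage cancer effect — a striking early hazard ratio fading
to near-null by year eight — without reproducing any particular dataset's
numbers.

## Problem sizes in the checks

The Monte-Carlo suites use n = 1000 with 500 replicates for PH-test
type-I error (99% binomial band [0.028, 0.078] around the nominal 5%),
200 replicates for power against the sine alternative, 300 replicates for
band coverage, and n = 3000 with 3 seeds for the decaying-HR recovery —
sizes at which the asymptotic Wald calibration is expected to hold and the
binomial bands are informative. The oracle-equivalence checks run at
n ≤ 100 where the expanded design is cheap to build exactly.
`scripts/acceptance.py` re-runs the same computations at 100 replicates
per operating characteristic.

## Known limitations

* Breslow only; with very heavy ties Efron would be less biased.
* A single λ for all covariates; effects with very different smoothness
  are pulled toward a compromise.
* Penalized variance is the non-sandwich inverse penalized information;
  bands under strong penalties are credible-interval-like and can
  undercover for sharply curved truths.
* The optimizer handles, but cannot repair, fundamentally unidentified
  fits (e.g. a binary covariate with no events in one arm late in
  follow-up); the conditioning diagnostic points to the penalized fit,
  which is the intended remedy.
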