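# Methods

## Problem and estimand

A diagnostic panel measures m continuous biomarkers X = (X₍₁₎, …, X₍ₘ₎)ᵀ on
each subject, with disease status Y ∈ {+1, −1}. The markers are combined
into a single score g(X); a subject is called diseased when g(X) exceeds a
cut-point c. The accuracy of the rule (g, c) is summarized by the Youden
index

    J = sen(g, c) + spe(g, c) − 1,

and the estimation target is the pair (g, c) maximizing J over a flexible
function class — not merely over linear combinations βᵀx, which are only
optimal in special cases (e.g. homoscedastic Gaussian classes; with
per-class covariances I₂ vs 2I₂ the ideal combination is already quadratic,
(x₁² + x₂²)/4 − (x₁ + x₂) at cut-point log 2 − 1).

## The kernel-machine estimator

Writing u = y (g(x) − c) for the functional margin, maximizing the
empirical weighted Youden objective is equivalent to minimizing a weighted
0–1 risk with inverse-prevalence weights ŵ(1) = n/|S₁|, ŵ(−1) = n/|S₋₁|.
The 0–1 loss is replaced by the truncated ramp ("psi-delta") surrogate

    L_δ(u) = min{(δ − u)₊/δ, 1},

and g is penalized by its squared RKHS norm, giving

    min_{a, c}  (1/n) Σᵢ ŵ(yᵢ) L_δ(yᵢ(Σⱼ aⱼ K(xᵢ, xⱼ) − c)) + (λ/2) aᵀKa,

a finite-dimensional problem by the representer theorem. Unlike the hinge
or logistic losses, the ramp saturates at 1, so no single hard observation
can dominate the weighted risk; it is also the form whose population
minimizer remains Fisher consistent in the covariate-adjusted extension.

### Optimization

L_δ is non-convex but admits the exact difference-of-convex split
L_δ(u) = (δ − u)₊/δ − (−u)₊/δ. The solver is a difference-of-convex
algorithm (DCA): at each iteration the concave part is linearized at the
current margins and the resulting convex piecewise-linear + quadratic
problem is solved exactly. Its dual is an SVM-like box-constrained QP with
a single equality constraint (from the unpenalized offset c),

    max_α  δ 1ᵀα − (1/2λ)(α − q)ᵀ YKY (α − q),
    0 ≤ αᵢ ≤ ŵᵢ/(nδ),  yᵀ(α − q) = 0,

where q carries the linearization (qᵢ = ŵᵢ/(nδ) when the current margin is
negative, else 0). No general-purpose QP library is required: the dual is
solved by SMO-style maximal-violating-pair updates (numba-compiled;
per-pair step in closed form, curvature floored at 1e−12 for duplicate
rows), and the offset c is then recovered by exact minimization of the
piecewise-linear primal in c over its breakpoints fᵢ − yᵢδ (smallest
minimizer on ties).

Numerical choices:

* initialization a = 0, c = 0, so the first DCA step is a weighted
  hinge-type fit at margin δ;
* concave-part subgradient at a zero margin taken on the inactive side (0);
* stopping at relative objective decrease < 1e−5 or 20 iterations;
* a new iterate is accepted only if the exactly evaluated objective does
  not increase, so the recorded objective trace is monotone by
  construction even under finite solver tolerance;
* SMO duality tolerance 1e−6 on the violating-pair gap.

### Tunable parameters

* `delta` (ramp width): 0.1 by default; smaller values track the 0–1 loss
  more closely but sharpen the non-convexity.
* `lambda` (RKHS penalty): selected by 5-fold stratified cross-validation
  maximizing the held-out empirical Youden index over the 81-point grid
  {10^((s−41)/10) : s = 1..81}; ties go to the smallest λ. The grid may be
  thinned (every k-th point) for faster runs.
* kernel: linear (LKME) or Gaussian (GKME). The Gaussian scale τ² is the
  square of the median cross-class pairwise Euclidean distance on the
  training set (median heuristic; unsquared distances enter the median,
  the result is squared — the alternative reading, median of squared
  distances, changes τ² only modestly and was not adopted). Even pair
  counts use the mean of the two central order statistics.

### Evaluation convention

Sensitivity counts scores strictly above the cut-point; a score exactly
equal to the cut-point is classified negative ("≤ c" indicators). The
optimal-cut-point search scans midpoints between consecutive distinct
scores plus sentinels beyond both extremes, returning the smallest
maximizing candidate on ties.

## Comparator methods

* **MVN** — per-class Gaussian plug-in: sample means/covariances, then the
  linear direction maximizing the binormal Youden index, optimized by
  Nelder-Mead over the unit sphere with 11 starts (Fisher direction + 10
  random); the cut-point is the closed-form density-crossing root of the
  two projected normals. A ridge of 1e−6·tr/m stabilizes near-singular
  covariances. The binormal objective (not the empirical J under plug-in
  normals) is used, since it has a closed-form cut-point.
* **MMM** — score = ±max_j x_j + γ·min_j x_j, γ grid-searched over
  {0, ±10^((s−41)/10)}; candidates ranked by their Youden-optimal training
  cut-point.
* **SWM** — markers enter by decreasing single-marker Youden index; each
  step adds γ·x_j to the running score with γ from the same signed grid
  (γ = 0 allowed).
* **LR** — maximum-likelihood main-effects logistic regression
  (scikit-learn); the score is the linear predictor and the default
  cut-point is predicted probability 1/2 (linear predictor 0) — the
  classification default, and the convention the benchmark reference
  values reflect; a Youden-optimized cut-point is available as an option.
  Perfect separation falls back to a ridge fit (C = 1000), flagged.

## Covariate-adjusted variant

The cut-point becomes a function c(z) in a second RKHS (kernel K₂ over
covariates Z, augmented with a +1 constant so c carries an intercept), the
weights become w(1, z) = 1/π_z, w(−1, z) = 1/(1 − π_z) with π_z estimated
by a main-effects logistic model (clipped to [0.01, 0.99]; a constant-π
fallback is available), and one λ penalizes ‖g‖² + ‖c‖² jointly. Because
the decision function g(x) − c(z) lives in the direct-sum RKHS with kernel
K₁ + K₂, every DCA subproblem optimum has opposite coefficient vectors
(b = −a), so the subproblem is a pure box QP over the summed kernel. With
the offset penalized, the dual is too ill-conditioned for coordinate-wise
updates at small λ (the rank-one offset direction has curvature ~n²/λ);
it is solved by L-BFGS-B instead. The target ramp width is reached by
continuation — fitting at δ = 0.5 and halving δ down to the requested
value, warm-starting each stage — which protects the non-convex DCA from
the poor local minima a cold start finds at small δ.

## Synthetic-data generators

The generators define the benchmark conditions (four markers, prevalence
1/2 in the class-conditional designs, training sizes 100/250/500, test
size 2000, 100 replications):

* **ex1** homoscedastic Gaussian classes, means (0.4, 1.0, 1.5, 1.2) vs 0,
  covariance 0.3 I₄ + 0.7 J₄ — the regime where linear combinations are
  Bayes optimal (Bayes J = 2Φ(Δ/2) − 1 ≈ 0.65).
* **ex2** multivariate gamma via a shared common shock: X_j = G₀ + G_j,
  G₀ ~ Gamma(1, 0.5), G_j ~ Gamma(k_j, 0.5) with k = (0.1, 0.4, 0.7, 1.0)
  for positives and 0.1 for negatives. This reproduces the stated class
  means and covariances exactly. A Gaussian-copula gamma sampler with
  moment-matched marginals (shape μ²/σ², scale σ²/μ; copula correlation =
  target Pearson correlation, no Nataf correction) is provided as
  `gamma_copula_sample`; its weaker tail dependence makes the classes
  measurably less separable than the common-shock model, which is why the
  common-shock form is the benchmark generator.
* **ex3** markers MVN(0, 0.3 I₄ + 0.7 J₄), labels from
  logit p = x₁ + x₂² + x₃³ + x₄⁴ − 1.5.
* **ex4** markers multivariate t₄ with scale matrix I₄ (so the marker
  covariance is 2 I₄ — the identity is read as the scale matrix), labels
  from logit p = 8(sin(πx₁/2) + cos(πx₁x₂) + x₃² + 3x₃x₄ + x₄²); the
  logit is clipped at ±500 before the logistic transform purely to avoid
  overflow.
* two bivariate toys (`toy_homo`, `toy_hetero`) for the linear-vs-quadratic
  ideal-rule illustrations.

Per-replication randomness is spawned from a single master seed
(`numpy` SeedSequence), so studies are bitwise reproducible and individual
replications can be re-derived. The study runner records failed
replications with a warning and excludes them from the summary; it reports
both the replication standard deviation and the standard error of the
mean.

What the generators do not emulate: measurement error and limits of
detection, missing markers, verification bias, non-random sampling of
cases and controls, and any covariate shift between training and test
draws. Passing benchmarks therefore demonstrates correctness of the
estimator under the stated sampling models, not robustness to those
real-data complications.

## Problem sizes used in the bundled reproduction

The bundled acceptance runs use the full protocol for the fast linear
comparators (100 replications) and a desk-scale protocol for the kernel
machines: 20 replications with the λ grid thinned 4× (21 points, still
spanning 1e−4…1e4). At these sizes the Monte-Carlo standard error of a
kernel-machine cell mean is ≈ 0.01–0.02. The analytic-toy check uses 10⁶
simulated points.

## Known limitations

* DCA finds stationary points, not global optima; with very weak
  regularization the objective is nearly flat and different solvers can
  return different, equally good rules (this is why the covariate variant
  uses δ-continuation).
* The MVN comparator's multi-start Nelder-Mead can in principle miss the
  global binormal direction for m well beyond the benchmark's m = 4.
* The Gaussian-copula gamma sampler matches marginal moments and
  correlations only approximately off the diagonal (no Nataf correction).
* No confidence intervals are produced for the fitted Youden index;
  perturbation-resampling inference and marker selection are out of scope.
* Fits are dense in n (Gram matrices are materialized); the intended
  regime is n ≤ a few thousand.
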