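# Methods

This note documents the statistical model, the numerical choices, the
synthetic benchmark, and the open design decisions behind `caseadapt`.

## Model and estimation

All classifiers are logistic models on augmented inputs x̃ = [1, x], with
x z-scored using training-split statistics (sample standard deviation,
n−1 denominator).  Every fit in the package maximizes one member of a
single family of objectives,

    J(w) = Σᵢ vᵢ log p(yᵢ | xᵢ; w) − ½ (w − m)ᵀ P (w − m),

with per-case weights v ≥ 0 and an optional Gaussian prior with mean m and
positive-semidefinite precision P:

| fit | v | m | P |
|---|---|---|---|
| baseline | 1 | — | — |
| full retrain (comparison arm) | 1 on train, 1+κ·kernel on retrieved | — | — |
| unregularized per-query ablation | β (similarity) | — | — |
| uniform prior (default) | β | w̄ | C·I |
| full-Hessian prior | β | w̄ | −∇²L(w̄) |
| varying prior | β | w̄_Var(x) | C·I |
| per-case pretraining (block i) | 1 (case i only) | w̄ᵢ | C′·(coupled) |

J is concave (strictly when P ≻ 0), so a damped Newton iteration — full
step, step-halving line search accepting only non-decreasing objective
values, 1e-8 ridge on the Hessian diagonal — converges to the global
maximum from any start.  Defaults: start at 0 for the baseline and at the
prior mean for every adaptive fit (the prior's center is the natural warm
start), gradient max-norm tolerance 1e-8, 100 iterations.  Log-sigmoid
terms use the overflow-safe `-log1p(exp(-|t|))` form, so margins of ±500
are handled exactly.

Two pathologies are guarded rather than allowed to crash. (1) With no
prior and a separable (often single-class) retrieved set the likelihood
supremum is not attained; the solver caps ‖w‖₂ at 1e6 and flags the fit.
(2) On separable training data the *gradient* still vanishes as
‖w‖ → ∞, so a gradient test alone would claim success with absurd
coefficients; a fit that satisfies the gradient test with ‖w‖ > 50 in
z-scored space (odds ratios ~ e⁵⁰ per standard deviation) is flagged as
non-converged with a separation warning.

Note that the attainable gradient norm at convergence is limited by the
1e-8 Hessian ridge; tolerances below ~1e-9 are not meaningful.

## Retrieval and weighting

Similarity is Euclidean distance in the z-scored feature space, so the
kernel bandwidth is comparable across features of different units.  The
bandwidth σ defaults to the 10th percentile (linear interpolation between
order statistics) of the N(N−1)/2 pairwise training distances; a fixed
literal value can be supplied instead, but any such value is
dataset-specific.  Retrieval takes the N_r smallest distances with ties
broken by library order (stable sort), which makes results deterministic
and permutation-checkable.  Weights βⱼ ∝ exp(−d²/σ²) are normalized to
sum to 1; if every kernel value underflows (all distances ≫ σ) the
weights fall back to uniform with a warning, since a zero weight vector
would make the objective degenerate.  A query's own id is excluded from
retrieval so a test case never informs its own classification.

## The coupled pretraining problem

The varying-prior scheme pretrains one vector per training case by
maximizing the coupled objective L̃ above, with w̄ᵢ the leave-one-out
kernel average of the other cases' vectors.  Two points deserve record:

*  The penalty is a positive-semidefinite quadratic form in the stacked
   vector (w₁, …, w_N), so the coupled problem is jointly concave.  The
   partial derivative of the penalty with respect to wᵢ contains, besides
   the obvious residual wᵢ − w̄ᵢ, cross terms through every other case's
   residual (wᵢ enters each w̄ₖ).  A Gauss–Seidel sweep that treats w̄ᵢ
   as a constant drops those cross terms: it neither ascends the true
   objective reliably nor stops at its stationary point.  Both solvers
   here therefore use exact derivatives.
*  The default solver is damped Newton on the stacked N(d+1)-dimensional
   system: the penalty Hessian C′(I−C)ᵀ(I−C) ⊗ I is constant and the
   likelihood Hessian is block-diagonal rank-one, so each iteration is one
   dense solve (175 cases × 10 parameters → a 1750² system, well under a
   second), and convergence is quadratic.  A block-coordinate alternative
   (`solver="block"`, exact block derivatives, each subproblem strictly
   concave) is retained; it increases the joint objective at every block
   update but, being first-order across blocks, approaches the optimum
   slowly and is mainly useful as an independent check of the Newton
   solution.

C′ = 0 is rejected as a precondition: each single-case likelihood is then
unbounded.  At the other extreme (C′ → ∞) the penalty forces all vectors
to a consensus, which the tests assert.  Interpolation of the query prior
mean w̄_Var uses all N training vectors without truncation.

## Evaluation

AUC is the empirical Mann–Whitney statistic, P(s₊ > s₋) + ½P(tie),
computed from average ranks; the stepwise ROC curve is constructed with
one vertex per distinct score so its trapezoidal area equals the rank AUC
identically (ties give diagonal segments).  Confidence intervals are
percentile bootstrap over case resamples (default 2000); single-class
resamples are redrawn and counted, and an input where more than half the
draws are single-class is rejected as too small or imbalanced.  Classifier
comparisons resample cases jointly and report
p = 2·min(frac(ΔAUC ≤ 0), frac(ΔAUC ≥ 0)) with an (n_boot+1)-denominator
correction, capped at 1.  A parametric binormal ROC fit is deliberately
not provided: the empirical AUC is assumption-free and admits an exact
O(n²) pair-counting oracle, which the tests use.

C and C′ are selected by stratified 10-fold cross-validation on the
training split, maximizing mean validation AUC over the grid
{0.001, 0.01, 0.05, 0.1, 0.2, 0.5, 1, 5, 10, 100}; within each fold the
k−1 training folds double as the retrieval library, so the validation
cases are classified by the same pipeline used at test time.  Ties break
toward the larger (more strongly regularized) candidate, a declared
convention.  Folds are refolded with a shifted seed if stratification
ever leaves a fold single-class.

## The synthetic benchmark

No public CADx case library exists, so the generator emulates the study
regime rather than any particular dataset: d = 9 features, three splits
of 175 (100 benign / 75 malignant), 175 (100/75), and 656 (446/210)
cases, drawn by rejection from the generative model so the class counts
are hit exactly.

Features are standard multivariate Gaussian.  The `locally_varying`
mechanism partitions feature space into K = 4 regions (Voronoi cells of
random unit anchor directions) and gives each region its own local
discriminant — slope norm 2.5, random direction, zero intercept — with
labels Bernoulli of the local logit divided by `noise_scale` (default 1).
These defaults were chosen once as a realistic middle ground: the
Bayes-optimal scorer reaches AUC ≈ 0.9 while a single global linear fit
loses ≥ 0.05 of AUC to the bent boundary, comparable to the headroom a
real case-adaptive system is built to claim.  `global_linear` is the
degenerate case in which all local discriminants coincide — the two
mechanisms consume the random stream identically, so equal local vectors
give byte-identical output, and the generator's truth metadata yields an
analytic Bayes scorer that upper-bounds every classifier.

What the benchmark does *not* emulate: realistic marginal distributions
of microcalcification features (skewness, heavy tails, inter-feature
correlation), measurement error in feature extraction, and
site-to-site distribution shift.  Passing the benchmark therefore shows
that the machinery works and that adaptation recovers locally varying
boundaries; it does not certify clinical performance on real lesions.

## Problem sizes and determinism

Tests and the acceptance script run the full study-sized benchmark
(175/175/656, 2000 bootstrap resamples) — each per-query refit is a
ten-parameter Newton solve and takes well under a millisecond, so the
whole suite completes in well under a minute.  Solver-fidelity checks run
on small instances (d ≤ 3, N ≤ 50) against `scipy.optimize.minimize`
(BFGS) as a generic, derivative-free-initialized maximizer.  Every source
of randomness (generation, bootstrap, folds) is an explicit seed;
identical seeds give bit-identical tables apart from recorded wall-clock
times, which are informational only.

## Known limitations

* The emphasis rule of the full-retrain comparison arm,
  βⱼ = 1 + κ·exp(−d²/σ²), realizes the required qualitative properties
  (weights > 1, decreasing with distance) but is a declared parametric
  surrogate, not a reconstruction of any specific earlier system.
* The per-query refit is linear; no kernelized variant is provided.
* Cross-validated selection reselects C per retrieval-count
  configuration; with very small training splits the CV folds' retrieval
  libraries (k−1 folds) can be smaller than N_r, in which case retrieval
  truncates to the available cases with a warning.
* The separation detector (coefficient norm threshold in z-scored space)
  is a heuristic; genuinely enormous effects and quasi-separation are not
  distinguishable from a finite sample.
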