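# Methods

This note records the statistical model, the algorithms, the defaults and the
design decisions behind `aftfuse`, and what the synthetic-data experiments do
and do not demonstrate.

## Model and estimand

Subjects arrive from two sources: a randomized trial (S=1) and an
observational real-world cohort (S=0). For potential log failure times
`log T~(a)` the estimand is the heterogeneous treatment effect
`τ(X) = E[log T~(1) − log T~(0) | X]`, modelled linearly, `τ(X) = Xᵀα`.
Randomization makes the arm contrast in the trial equal `τ`; in the RWD the
contrast may differ by a confounding function `uc(X) = Xᵀβ`, the bias
induced by unmeasured confounders. Assumptions: consistency, randomization
within the trial, a common `τ` across sources (no effect modification by
trial participation beyond X), and linear working models for `τ` and `uc`.

Subtracting the conditional mean `μ(X,S) = E[log T~ | X,S]` gives the
residualized (Robinson-type) regression

    log T~ − μ(X,S) = (A − e(X,S)) · Uᵀθ + ε,    U = (1, X, 1−S, (1−S)X),

whose score is first-order insensitive (Neyman-orthogonal) to errors in the
nuisances `η = (e, μ)`. Censoring is handled by Stute/Kaplan–Meier jump
weights: sorting by observed time, weight
`w₁ = δ₍₁₎/n`, `wᵢ = δ₍ᵢ₎/(n−i+1) · Π_{j<i} ((n−j)/(n−j+1))^{δ₍ⱼ₎}`
is the product-limit mass at the i-th ordered time; censored rows get exactly
zero weight and the weighted empirical measure consistently estimates
expectations over the joint law of (Z, A, T~) on the censoring support. Ties
are ordered events-first, then by original row (the standard product-limit
convention); a censored maximum leaves total mass < 1 and is reported as
`StuteWeights.total_mass`, with no redistribution.

Sparsity and confounding detection come from separate folded-concave
penalties on the α and β covariate blocks (both intercepts unpenalized).
`confounding_detected` is true iff some penalized β̂ⱼ is exactly nonzero.

## Algorithms

**Penalized solver.** The design has 2p+2 columns, so the solver works on
the Gram matrix G = XᵀWX: one coordinate update costs O(p) independent of n,
and the inner loop is numba-compiled. The scalar update is the exact proximal
operator of MCP (default γ=3), SCAD (γ=3.7) or the adaptive lasso.
Penalized columns are rescaled to unit Stute-weighted second moment (no
centering — every column carries the factor A−ê, so the span contains no
constant and centering would change the model); coefficients are mapped back
afterwards. Convergence: max coefficient change < 1e-7, at most 1000 sweeps.

Because the objective is nonconvex, every path point is solved from two
starts — warm (neighbouring grid solution) and cold (zero) — keeping the
lower penalized objective; single fixed-λ solves additionally try the
unpenalized WLS start. Without this, warm-started paths occasionally track
inferior local minima (e.g. losing a true β coordinate as λ₁ grows), which
destabilizes tuning.

**Tuning.** The λ grid is the cross product of per-block log-spaced grids
(15 points each) from λmax (the largest absolute weighted gradient at the
zero solution, unpenalized columns profiled out) down to 0.01·λmax. K=5-fold
CV recomputes Stute weights on every training and validation subsample
(Kaplan–Meier masses are sample-dependent). The default selection is a
structured one-standard-error rule: find the CV minimizer; form the *paired*
fold-SE of error differences to it (fold errors are strongly correlated
across the grid, so the paired SE — not the level SE — is the relevant
uncertainty); among in-band candidates with the minimizer's β support, take
the largest λ₁. This guards against occasional anomalously deep CV minima,
which otherwise dominate the false-discovery rate. A final *confounding
parsimony* check prefers a solution with the entire β block zero whenever one
cross-validates within twice the paired SE of the selected point — Occam's
razor on the confounding explanation; with a genuinely confounded source the
β-free fit is far outside any reasonable band and the check never triggers.
Plain `min`, unstructured `1se` variants and BIC
(`n·log(loss) + df·log n`, df = nonzero count, ties toward larger λ₁+λ₂)
are available.

**Nuisances.** Cross-fitting (default K=2, folds stratified by source ×
treatment) keeps each subject's predictions independent of its own fold.
The propensity is a logistic regression on (X, S), clipped to [0.01, 0.99];
a known trial randomization probability can be injected. The outcome mean
uses the arm-combination estimator
`μ̂ = ê·μ̂₁ + (1−ê)·μ̂₀`, with each arm mean a Stute-weighted least-squares
fit on the basis [X, S, (1−S)X, X², X³]. Fitting within arm matters under
censoring: a pooled regression of log T on (X,S) must absorb the treatment
effect into its residual, and when the outcome spread exceeds the censoring
support the weighted projection is strongly distorted; the arm-wise fits have
far smaller conditional variance and the combination is exact by the law of
total expectation. The polynomial terms track smooth nonlinear baselines
(quadratic and sinusoidal trends) without inviting the wild extrapolation of
a full high-order interaction basis. Pooled 'linear', 'polyridge' and 'gbt'
learners exist behind the same interface; in our experiments every pooled
learner inflated the estimator's error several-fold under heavy-tailed
outcomes with 20–40% censoring.

**Estimator variants.** The trial-only variant re-runs the identical
pipeline on the S=1 subsample with its own cross-fitted nuisances, so it is
computable from trial data alone. The naive variant drops the β block but
keeps the pooled sample (shared nuisances). Oracle fits solve unpenalized
Stute-weighted least squares on supplied supports plus intercepts.
Comparators (outcome-adjusted/AIPW, μ₀-based, μ₁-based, their sample-size
meta-combination, and the fully imputed μ₁−μ₀ regression) all reduce to
penalized regressions of a pseudo-response on [1, X, 1−S, (1−S)X] with the
same machinery; the imputed-response comparator uses uniform 1/n weights
since its response contains no observed outcome.

**Bootstrap.** Standard errors come from an m-out-of-n bootstrap:
m = round(0.632·n) subjects drawn without replacement, stratified by source;
Stute weights recomputed per subsample; (λ₁, λ₂) and nuisance predictions
held at their full-data values; invalid subsamples (losing an arm, a source,
or all events) are redrawn (at most 100 times). Because an m-subsample
estimate differs from the full-data one with variance ≈ V(1/m − 1/n), the
raw spread is rescaled by √(m/(n−m)) to the level-n standard error —
without this the SE underestimates the sampling SD by ~24%. Intervals are
normal (point ± z·SE), matching how coverage is evaluated.

## Synthetic data generator

The generator emulates a two-source study with n=2500 subjects (≈20% trial),
p ∈ {20, 50} covariates with AR(0.3) correlation and a 0.2·A mean shift on
the first eight coordinates, log failure times

    log T~ = sin X₁ + 0.2 X₄² − 0.5 Xᵀα* − 0.5 (1−S) Xᵀβ* + A Xᵀα* + (1−S) u + ε,

α* = ±Signal on eight coordinates (Signal=2 by default), β* = ±Signal on
four coordinates when confounded, u | A ~ N(A·Xᵀβ*, 1) the scalar
unmeasured confounder (absent entirely in unconfounded scenarios — "no
unmeasured confounding" means no u, not a zero-mean u), ε standard normal
(a logistic option gives log-logistic failure times). Censoring is uniform
on the log scale over a width-4 window whose location is calibrated by
bisection on a 100,000-draw pilot so the realized censoring rate hits the
target (20% or 40%) within ±0.005. Exact nuisance functions (the propensity
is logistic-linear by Gaussian discriminant algebra) are exported for
oracle-nuisance testing.

What passing tests on this generator do *not* show: performance under
covariate-dependent censoring, misspecified `τ`/`uc` link functions,
non-Gaussian covariates, or informative trial participation — none of which
the generator produces.

## Known limitations

* With uniform censoring on a narrow window, subjects whose log failure time
  exceeds the window top are never observable (the failure-time support
  exceeds the censoring support). The Stute-weighted estimand is then an
  attenuated version of θ*: at the default study conditions the fitted
  coefficients are biased toward zero by ≈2–3% of their magnitude. This
  attenuation is a property of the weighted least-squares framework itself,
  shrinks as the censoring window widens, and is invisible to the subsampling
  bootstrap (every subsample shares it), so confidence intervals for large
  coefficients undercover at the default conditions (≈0.80–0.90 observed
  vs 0.95 nominal for coefficients of magnitude 2).
* Selection by any within-sample cross-validation validates dataset-level
  spurious correlations of order σ/√n; occasional false discoveries of that
  magnitude survive every CV variant we tested. The structured 1-SE rule
  keeps the false-discovery rate at the percent level; BIC is sparser.
* The bootstrap holds tuning and nuisances fixed, so its SE omits selection
  and nuisance-estimation variability.
* Inference after model selection is reported per coefficient without
  selective-inference correction.
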