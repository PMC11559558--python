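# Methods

## Model

A Gaussian graphical model (GGM) couples an undirected graph on p nodes with
a multivariate normal distribution N(0, Σ).  An edge (i, j) is absent exactly
when X_i ⊥ X_j given all remaining variables, which for Gaussian data is
equivalent to a zero in the precision matrix Θ = Σ⁻¹.  Estimation is
nodewise: each variable is regressed on all others,

    X_i = Σ_{j≠i} X_j β_ij + e_i,     e_i ~ N(0, σ_e²),

and the identity β_ij = −Θ_ij/Θ_ii links the regression coefficients to the
precision matrix; ρ_ij = −Θ_ij/√(Θ_ii Θ_jj) is the partial correlation, and
ρ_ij² = β_ij β_ji.  The p neighborhoods are stitched into one network; under
the *and*-rule an undirected edge is kept only when both of its two ordered
decisions are positive.

All fits center columns and carry no intercept.  Penalized fits standardize
columns to unit variance first and report coefficients on the original
scale; the penalty is therefore unit-free.

## Why the plain lasso cannot carry inference

The lasso both shrinks and selects: estimates are biased toward zero and sit
exactly at zero with positive probability, so its sampling distribution is
discontinuous and naive bootstrap quantiles are not confidence intervals.
The package demonstrates this directly (`bootstrap_lasso_distribution`): on
the nine-edge benchmark model the pairs-bootstrap distribution of the lasso
estimate for a true partial correlation of 0.5 at n = 500 sits entirely
below 0.5 in most runs, and absent edges collapse to a point mass at zero.

Three inference methods with valid frequentist guarantees are provided.

### Desparsified (debiased) lasso

For the regression of y = X_i on X = X_{−i}, with lasso estimate b and
score projections Z_j (the residual of a lasso regression of column X_j on
the remaining columns),

    b^d_j = b_j + Z_j'(y − Xb) / (Z_j'X_j),
    se_j  = σ̂_ε ‖Z_j‖₂ / |Z_j'X_j|.

The correction removes the shrinkage bias; b^d is approximately Gaussian, so
p-values and CIs follow from the normal reference.  σ̂_ε² is the outer-lasso
residual variance with the degrees-of-freedom correction RSS/(n − ŝ), ŝ the
selected-set size.  At the unpenalized solution the correction vanishes
identically and b^d equals OLS (a test pins this to 1e-6).  Projection
penalties default to the same 10-fold CV as the outer fit; a theoretical
scaling √(ln p / n) is available via `inner="fixed"`.  Z columns are not
rescaled, keeping the orthonormal-design identity b^d_j = X_j'y/n exact.

### Multi sample-splitting

Half the sample selects each node's neighborhood (CV lasso); the other half
yields classical OLS t-test p-values restricted to the selected edges
(p = 1 for unselected edges), corrected per node by the selected-set size
|Ŝ₁|.  K = 50 splits are aggregated through the empirical-quantile rule
Q(γ) = min{1, γ-quantile of {p_k/γ}} over γ ∈ [0.05, 1] (100 log-spaced
points), with final p = min{1, (1 − ln 0.05)·min_γ Q(γ)}.  The aggregated
p-value embeds its own multiplicity control, so no further Holm pass is
applied to multisplit output.  The method emits p-values only: its intervals
are known to undercover (it was designed for testing), and the package
deliberately does not construct them.  If a node selects ≥ n₂ edges the
selection is truncated to the n₂ − 1 largest coefficients with a warning.

### Pairs bootstrap of the desparsified lasso

Whole rows are resampled with replacement (respecting the joint
distribution); the desparsified fit is recomputed on each of K ≥ 500
resamples with penalties frozen at the original CV choices (`recv=True`
re-runs CV per resample).  CIs are percentile intervals (order statistics
⌈Kα/2⌉ and ⌊K(1−α/2)⌋); the two-sided p-value is the empirical tail
probability of zero, 2·min(F̂(0), 1−F̂(0)), with a +1 continuity correction
so p > 0.  Percentile rather than BCa intervals: simplest method consistent
with using the empirical distribution, and the debiased estimates are close
to Gaussian.  Residual (model-based) bootstrap is deliberately out of scope.

## Multiple testing and decisions

A p-node network has m = p(p−1) ordered tests.  OLS, desparsified and
bootstrap p-values are Holm step-down corrected as one family of m tests
(via statsmodels); edges are decided by the and-rule at family-wise level
α = 0.05.  CIs are reported at the per-interval level by default; a
`simultaneous` flag switches to α/m.  The package also reproduces, verbatim,
a published worked example whose correction factor is printed as m − i − j
(378 for m = 380, 10 for |Ŝ₁| = 12); that formula differs from standard Holm
indexing (m − rank + 1) and is kept only in
`inference.printed_correction_factor` for checking the worked-example
arithmetic — the pipeline always uses standard Holm.

## Synthetic truth generator

`generate_random_graph(p, pe)` places each unordered pair independently with
probability pe (benchmarks: p = 20, pe ∈ {0.2, 0.4}).  Edge weights are
drawn Uniform(0.1, 0.8) — positive, matching the benchmark range; no random
sign flips.  Positive definiteness is repaired by diagonal loading
(Θ = Θ₀ + (|λ_min(Θ₀)| + 0.1)I) followed by rescaling to unit diagonal.
Because the loading is a single scalar, the repair preserves the support
and the rank order of the weights, and −Θ_ij equals the model's partial
correlation.  The repair does shrink magnitudes: a raw weight of 0.8 maps to
a partial correlation well below 0.8 in dense graphs.  Gaussian samples come
from N(0, Θ⁻¹) via Cholesky.  All randomness flows from one integer seed
through numpy's default PCG64 generator.

The nine-edge benchmark model (`fig2_model`) has partial correlations 0.1,
0.2, …, 0.9 placed on vertex-disjoint pairs (1,2), (3,4), …, (17,18), with
two isolated nodes; each 2×2 precision block [[1, −ρ], [−ρ, 1]] inverts in
closed form, so the stated correlations are exact.

Assumption diagnostics: the sparsity allowance is s(n, p) = ⌊√(n/ln p)⌋
(≈ 4 at n = 50, ≈ 12 at n = 500 for p = 20) and the beta-min detectability
floor is d(n, p) = √(ln p / n) (≈ 0.25 at n = 50, ≈ 0.08 at n = 500).  These
square-root forms are adopted because they reproduce all four benchmark
values consistently; logs are natural.  The closed-form fraction of
Uniform(0.1, 0.8) weights above d is (0.8 − d)/0.7 clipped to [0, 1] —
about 79% at n = 50.

## What the generator does and does not emulate

The generator produces exactly Gaussian, i.i.d., mean-zero data with a
sparse stationary truth.  It does not emulate heavy tails, ordinal or
skewed margins, missingness, dependent sampling, or model misspecification
(e.g. latent confounders).  Passing tests therefore certify the estimators'
behavior under a correct GGM; real psychological or biological data will
typically degrade coverage and precision in ways these simulations cannot
reveal.

## Numerical choices

* **Lasso solver.**  Cyclic coordinate descent on the Gram matrix,
  warm-started along a 100-point log-spaced penalty grid from λ_max =
  max_j |X_j'y|/n down to 10⁻⁴λ_max.  Each penalty finishes with an exact
  solve of the KKT system on the stabilized active set, so path solutions
  agree with sklearn's `lasso_path` to ~1e-12 while remaining fast deep in
  the path.  The kernel is numba-compiled; a test pins `cv_lasso` against
  sklearn's `LassoCV` on identical grids and folds.
* **Cross-validation.**  10-fold, shuffled with a seeded `KFold`;
  fold-averaged MSE; the λ grid is computed once on the full data (as in
  glmnet).  Single-λ fits warm-start down a 30-point path from λ_max.
* **Degenerate inputs.**  Constant columns are rejected with the offending
  column named; perfectly collinear projection columns raise a
  singular-projection error; OLS refuses n ≤ p; λ_max ≈ 0 (response
  orthogonal to the design) returns the zero solution.
* **Ties and caps.**  p-values are capped at 1; Holm uses the running
  maximum; percentile CI ranks are clamped to [1, K].
* **EBIC graphical lasso.**  Fit on the correlation matrix over a 30-point
  log grid; EBIC(γ) = −n(logdet Θ − tr(SΘ)) + E ln n + 4γE ln p with γ = 0.5
  by default (γ = 0 is BIC); solver failures at individual penalties are
  counted and skipped.

## Problem sizes used by the test suite and acceptance script

Simulation-backed checks run at deliberately chosen desk scales: coverage
uses 20 replicates of the sparse benchmark condition (p = 20, pe = 0.2,
n = 500); the bootstrap illustration uses one n = 500 dataset and K = 1000
resamples; the family-wise-error check under the global null uses 500
replicates at p = 5, n = 100; qualitative method-ordering comparisons pool
recovery counts over 20 paired datasets with K = 5 splits for the
multisplit.  These sizes give binomial standard errors comfortably inside
the asserted tolerances while keeping a full run in minutes on one core.

## Known limitations

* Coverage and error control are asymptotic; at n ≈ p both desparsified and
  OLS intervals degrade (the simulation engine makes this visible).
* The multisplit aggregation constant (1 − ln γ_min) is conservative; its
  p-values are not comparable in magnitude across different γ_min.
* The bootstrap with frozen penalties understates penalty-selection
  variability; `recv=True` restores it at ~20× cost.
* Estimation-only methods (lasso, thresholded lasso, EBIC glasso) provide no
  uncertainty; their `GGMResults` carry no edge table.
* Under the and-sign rule an absent edge's bootstrap-lasso estimate is not
  always exactly zero at n = 500: when cross-validation on the original
  data lands on an interior penalty for a null regression, a minority of
  resamples produce sign-agreeing nonzero pairs.  The point-mass-at-zero
  picture is typical but not universal across seeds.
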