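# ggminfer

**Edge-level frequentist inference for Gaussian graphical models estimated by
nodewise lasso regression.**

Partial-correlation networks are usually estimated with the lasso, which
selects edges by setting small coefficients exactly to zero.  That same
property breaks classical inference: the lasso's sampling distribution is
biased and has a point mass at zero, so its bootstrap quantiles are not
confidence intervals and it yields no p-values.  `ggminfer` is for
researchers — e.g. in psychopathology, systems biology, or any field that
fits Gaussian graphical models (GGMs) — who want edge decisions *with*
quantified uncertainty: p-values corrected for family-wise error and
confidence intervals with honest coverage.

## The model and the estimators

A GGM ties an undirected graph to a multivariate normal N(0, Σ): an edge
(i, j) is present iff the precision-matrix entry Θ_ij = (Σ⁻¹)_ij ≠ 0,
equivalently the partial correlation ρ_ij = −Θ_ij/√(Θ_ii Θ_jj) ≠ 0.
Estimation is nodewise: regress each X_i on the rest,
X_i = Σ_{j≠i} X_j β_ij + e_i, with β_ij = −Θ_ij/Θ_ii, and combine the two
ordered decisions per pair with the *and*-rule.

Inference methods (per-edge p-values, Holm-corrected over all p(p−1) ordered
tests, and CIs where meaningful):

| method | idea |
|---|---|
| `desplasso` | desparsified (debiased) lasso: b^d = b + Z'(y − Xb)/(Z'X_j); approximately Gaussian, analytic SEs |
| `desplasso_boot` | pairs bootstrap of the debiased estimates; percentile CIs, empirical p-values |
| `multisplit` | lasso selection on one half-sample, OLS t-tests on the other, K splits aggregated by an empirical-quantile rule (p-values only) |
| `ols` | classical unpenalized regression t-tests (needs n > p) |

Estimation-only comparators: `lasso`, `lasso_thresholded`, `glasso_ebic`
(graphical lasso with EBIC penalty selection).  A synthetic-GGM engine
(random graphs, Uniform(0.1, 0.8) edge weights, positive-definite repair)
generates ground truth and scores sensitivity, precision, specificity and CI
coverage for every method.  See `docs/methods.md` for formulas, defaults and
limitations.

## Worked example

```python
from ggminfer import GGM, SimulationDesign, simulate_dataset

model, data = simulate_dataset(SimulationDesign(p=10, pe=0.2, n=300, seed=7))
res = GGM(data).fit(method="desplasso", alpha=0.05, seed=1)
print(res.summary())
```

```
Gaussian graphical model inference
==========================================================
method: desplasso              nodes: 10
alpha (family-wise): 0.05      rule: and
ordered tests: 90              significant edges: 7
----------------------------------------------------------
edge                     rho_hat     beta_hat
X1 -- X7                    0.517        0.518
X4 -- X10                   0.500        0.500
X7 -- X8                    0.408        0.408
X4 -- X8                    0.387        0.387
X3 -- X5                    0.379        0.381
X3 -- X4                    0.376        0.377
X8 -- X10                   0.196        0.196
==========================================================
```

The generating truth here has 8 edges; the seven listed pairs are all true
edges (`rho_hat` is the estimated partial correlation, `beta_hat` the
averaged regression coefficient), one weak true edge is missed, and no false
edge survives the Holm + and-rule screen at family-wise α = 0.05.  Per-edge
detail lives in `res.edge_table`:

```
 i  j name_i name_j  estimate     se  p_raw  p_corrected  ci_lower  ci_upper  significant
 0  1     X1     X2   -0.1013 0.0555 0.0680          1.0   -0.2101    0.0075        False
 0  2     X1     X3    0.0504 0.0564 0.3713          1.0   -0.0601    0.1610        False
 ...
```

`res.plot_ci()` draws the CI ladder; `res.save(dir)` writes TSV/CSV tables.
The same pipelines are scriptable from a shell:

```bash
ggminfer simulate --p 20 --pe 0.2 --n 500 --seed 1 --out run/
ggminfer infer --data run/data.csv --method desplasso --alpha 0.05 --out run/
ggminfer evaluate --grid small --methods ols,desplasso,lasso --reps 10 --out run/
ggminfer replicate-fig2 --n 500 --boot 1000 --out run/
```

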