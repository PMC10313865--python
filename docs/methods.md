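# Methods

This note records the statistical procedures, their numerical implementation,
and the design decisions taken where a choice had to be made.

## 1. Data-generating process

One simulated trial has two strata, each containing `clusters_per_stratum`
clusters of `cluster_size` individuals, with exactly half the clusters in each
stratum assigned to treatment. Outcomes follow the random-intercept model

```
Y_ijks = beta0 + beta1 * X_jks + beta2 * S_jks + C_jks + e_ijks
C_jks ~ N(0, sigma_b^2),  e_ijks ~ N(0, sigma_e^2)   (independent)
```

The variance components are parameterized by the intracluster correlation
`icc = sigma_b^2 / (sigma_b^2 + sigma_e^2)` with the total fixed (default 1),
so `beta1` is an effect in total-SD units.

**Defaults and grid.** `beta0 = 0` and `total_variance = 1` (location/scale
are irrelevant to the operating characteristics; tests verify the analyses are
location/scale equivariant). The study grid is clusters-per-stratum
{6, 24, 34, 68}, cluster size {5, 10, …, 50}, ICC {0.03, 0.06, 0.10} (the
range typical of community/clinic CRTs), `beta1` ∈ {0, 0.11, 0.50} (null,
small, large) and `beta2` ∈ {0.11, 0.50}.

**What the generator emulates — and does not.** It captures the essential
structure: within-cluster correlation, stratification with exact 1:1
allocation, and additive stratum effects. It deliberately does **not** model
varying cluster sizes, more than two strata, unequal strata, non-normal
outcomes, missing data, covariates beyond the stratum, or treatment-effect
heterogeneity. Allocation is deterministic (first half of each stratum's
clusters treated); because cluster effects and errors are exchangeable i.i.d.
draws, this is distributionally identical to randomizing the labels, and a
test verifies that a permuted allocation reproduces the same trials.

**Reproducibility contract.** The draw order per replicate is fixed: first the
K cluster effects, then the K×n error matrix. Each grid cell derives a
`SeedSequence` whose entropy is (master seed, cell parameters), and each
replicate gets a spawned child stream. Consequences: a cell's replicates are
identical whether the cell is run alone or inside any grid; all four methods
analyze the same data (common random numbers), so method contrasts are paired;
and the vectorized engine and per-dataset path generate bit-identical data.

## 2. The four analyses

All model the mean as `beta0 + beta1*arm + beta2*stratum` (p = 3 fixed
effects) and test H0: beta1 = 0 at alpha = 0.05 with 95% CIs.

### Linear mixed model (`lmm`)
Random-intercept model fit by REML. The likelihood is profiled to one
dimension, lambda = sigma_b^2/sigma_e^2, using the Woodbury identity
`(I + lambda*J)^-1 = I - lambda/(1+n*lambda) * J` on per-cluster sufficient
statistics, so a fit is O(K) regardless of cluster size. The profile is
minimized by bounded Brent search on log(lambda) in [−25, 14] (xatol 1e−10),
with an explicit check of the lambda = 0 boundary; at the boundary the model
collapses to OLS with N−p residual df. Inference uses a t test with
**Satterthwaite** df: `nu = 2 v^2 / (g' A g)` where `v = Var(beta1_hat)`, `g`
its gradient in (sigma_b^2, sigma_e^2) — computed **analytically** — and `A`
the asymptotic covariance of the variance components, taken as twice the
inverse of a central-finite-difference Hessian of the −2 REML log-likelihood
with relative step 1e−3 (floored at 5% of the total variance). The larger step
matters: second differences at step 1e−5 lose the curvature to rounding near
the sigma_b^2 = 0 boundary and corrupt the df. For balanced designs the
interior Satterthwaite df is exactly K−3, which tests verify to 1e−6; the
implementation also matches R's lmerTest (estimates, SE, df, p, REML
criterion) and statsmodels MixedLM on reference data.

### GEE (`gee`)
Exchangeable working correlation; alpha and the scale phi estimated by the
standard moment estimators with p-corrected denominators, iterated with GLS
updates of beta to convergence (tol 1e−8). Variance of beta1_hat is the
Liang–Zeger robust sandwich estimate. The test is the 1-df Wald chi-square
(statistic z², as is conventional for GEE software); the 95% CI is the Wald
normal interval `beta1_hat ± 1.96 se`. Matches statsmodels GEE (beta, alpha,
phi, robust SE) to 1e−8. No small-sample correction is applied — the point of
the comparison is the behaviour of the uncorrected sandwich.

### Cluster-level regression (`cl_regression`)
OLS of cluster means on arm + stratum; t test on **K−3** df (K clusters, 3
regression parameters — the standard OLS residual df). With equal cluster
sizes this weights clusters equally, which is efficient here.

### Meta-regression (`meta_regression`)
Within each stratum, the difference in arm means of cluster means, with
variance `s_t²/m_t + s_c²/m_c` from the between-cluster sample variances. The
two stratum effects are pooled by **fixed-effects (common-effect)
inverse-variance** weighting with a z test. Fixed-effects pooling is the
appropriate choice because the generating model has a common treatment effect
across strata; with only two strata a random-effects heterogeneity variance is
essentially inestimable.

On this balanced design all four point estimates of beta1 coincide exactly
(the GLS/GEE/OLS estimators all reduce to OLS on cluster means); the methods
differ only in `se`, df and reference distribution. This is derived in closed
form and exploited by the harness (below).

## 3. Monte Carlo harness and metrics

Per cell, R replicate trials are generated and analyzed by all four methods.
Metrics over the converged replicates:

- **rejection rate** (type I error under beta1 = 0; power otherwise), with
  Monte Carlo SE sqrt(r(1−r)/R_conv);
- **RMSE** = sqrt(mean((beta1_hat − beta1)²)) — the root is applied since the
  quantity is a root-mean-square error;
- **mean 95% CI width** and **coverage** (CI contains the true beta1), with
  binomial MC SE;
- bookkeeping: mean estimate, mean SE, convergence count.

Replicates where a method fails (e.g., a degenerate stratum variance in
meta-regression) are **excluded from that method's metrics** and counted in a
convergence log; in the study grid failures are essentially absent.

**Engines.** The `direct` engine runs the general per-dataset fitters. The
default `balanced` engine evaluates the same estimators through closed forms
on cluster means and within-cluster sums of squares (REML has an explicit
solution in balanced two-level designs; the sandwich reduces to HC0 on cluster
means). Tests pin the two engines replicate-by-replicate to 5e−7 on shared
random substreams. The balanced engine makes the full study (210 cells × 1000
replicates × 4 methods) run in tens of seconds.

**Problem sizes.** The headline campaigns (`stratcrt.study`) use 1000
replicates per cell — enough that a 5% rejection rate has MC SE ≈ 0.7
percentage points per cell, and ≈ 0.2 points after averaging over the ten
cluster sizes, comfortably inside the ±2/±3-point tolerances used in the
acceptance tests. Cross-size averages refuse to compute if any cluster size is
missing, so an aggregate can never silently average over a partial grid.

## 4. Known limitations

- Balanced designs only: equal cluster sizes, equal strata, exact 1:1
  allocation. The closed-form engine and the K−3 df identity both rely on
  this; the general fitters accept unbalanced data but are not the tested
  regime.
- Two strata, one cluster-level randomization factor, normal outcomes.
- GEE uses the asymptotic sandwich without finite-sample corrections
  (Kauermann–Carroll, Fay–Graubard, …) — by design, since quantifying the
  uncorrected small-sample behaviour is the object of study.
- The Satterthwaite variance-component covariance comes from a
  finite-difference Hessian; near the boundary the df is governed by the
  explicit boundary branch (OLS, N−p df) rather than the quadrature.
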