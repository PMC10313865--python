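# stratcrt

Simulation and analysis toolkit for **stratified cluster randomized trials
(CRTs) with continuous outcomes**. It implements a Monte Carlo comparison of
four stratification-adjusted analysis methods — a linear mixed model, GEE with
the robust sandwich variance, cluster-level linear regression, and fixed-effects
meta-regression of per-stratum effects — across realistic numbers of clusters,
cluster sizes, and intracluster correlations.

## The problem

In a CRT, whole clusters (clinics, schools, villages) are randomized, so
outcomes of people in the same cluster are correlated. Trials are often
*stratified* — randomization is balanced within strata (e.g., region) — and the
analysis should adjust for the stratification. Several adjusted methods exist;
they agree asymptotically but can behave very differently with the small
numbers of clusters typical of real CRTs. This package quantifies those
differences by simulation: type I error, power, RMSE of the effect estimate,
and 95% confidence-interval width and coverage.

## Data-generating model

Outcomes for individual $i$ in cluster $j$ of stratum $s$ and arm $k$:

$$Y_{ijks} = \beta_0 + \beta_1 X_{jks} + \beta_2 S_{jks} + C_{jks} + e_{ijks}$$

with treatment indicator $X$, stratum indicator $S$ (two strata), random
cluster effect $C_{jks} \sim N(0, \sigma_b^2)$ and error
$e_{ijks} \sim N(0, \sigma_e^2)$. The variance components are set from the
intracluster correlation coefficient,
$\rho = \sigma_b^2 / (\sigma_b^2 + \sigma_e^2)$, holding the total variance at
1, so effects are in standard-deviation units. Clusters are allocated 1:1
within each stratum.

## The four analysis methods

| method | estimator | test |
|---|---|---|
| `lmm` | random-intercept linear mixed model, REML | t test, Satterthwaite df |
| `gee` | exchangeable GEE, Liang–Zeger sandwich variance | 1-df Wald chi-square |
| `cl_regression` | OLS on cluster means (arm + stratum) | t test, K−3 df |
| `meta_regression` | per-stratum mean differences pooled by fixed-effects inverse-variance meta-analysis | z test |

All four target the same marginal treatment effect $\beta_1$; on this balanced
design their point estimates coincide and only their variance estimates and
reference distributions differ. See [docs/methods.md](docs/methods.md) for the
estimators, numerical choices, and design decisions.

## Worked example

```python
import dataclasses
import numpy as np
import pandas as pd
from stratcrt import SimScenario, analyze_all, generate_trial

scenario = SimScenario(
    clusters_per_stratum=24, cluster_size=30, icc=0.06, beta1=0.5, beta2=0.11
)
trial = generate_trial(scenario, np.random.default_rng(7))
results = analyze_all(trial)
print(pd.DataFrame([dataclasses.asdict(r) for r in results.values()])
      [["method", "estimate", "se", "df", "ci_low", "ci_high"]].round(4))
```

prints (true effect 0.5):

```
         method  estimate     se   df  ci_low  ci_high
            lmm    0.5049 0.0849 45.0  0.3338   0.6760
            gee    0.5049 0.0822  inf  0.3437   0.6661
  cl_regression    0.5049 0.0849 45.0  0.3338   0.6760
meta_regression    0.5134 0.0825  inf  0.3518   0.6751
```

A small null-hypothesis Monte Carlo grid (see `examples/03_run_small_grid.py`)
shows the headline phenomenon — sandwich-based tests are anti-conservative with
few clusters:

```
         method  clusters_per_stratum  cluster_size  rejection_rate  coverage
            lmm                     6            10           0.056     0.944
            gee                     6            10           0.110     0.890
  cl_regression                     6            10           0.056     0.944
meta_regression                     6            10           0.144     0.856
```

The `examples/` directory has five short scripts, one per capability:
simulating a trial, analyzing it four ways, running a grid, computing the
headline study summaries, and pivoting results into figure-style tables. A
thin CLI mirrors the first three: `stratcrt simulate`, `stratcrt analyze`,
`stratcrt run-grid`.

## Layout

- `src/stratcrt/` — `simulate` (generator), `lmm`, `gee`, `cluster_level`
  (the four analyses), `harness` (Monte Carlo engine + metrics), `study`
  (headline campaigns), `figures` (summary pivots/plots), `cli`
- `tests/` — unit tests with analytic and statsmodels/lmerTest oracles,
  property-based tests, and `test_acceptance.py` (end-to-end operating
  characteristics)
- `examples/`, `scripts/acceptance.py`, `docs/methods.md`
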