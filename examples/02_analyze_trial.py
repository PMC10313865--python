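"""Analyze one simulated trial with all four stratification-adjusted methods.

The four estimators of the treatment effect:
  lmm             random-intercept linear mixed model (REML), t test with
                  Satterthwaite degrees of freedom
  gee             exchangeable GEE with the Liang-Zeger robust (sandwich)
                  variance, 1-df Wald chi-square test
  cl_regression   OLS on cluster-level means, t test on K-3 df
  meta_regression per-stratum mean differences pooled by fixed-effects
                  inverse-variance meta-analysis, z test
"""

import dataclasses

import numpy as np
import pandas as pd

from stratcrt import SimScenario, analyze_all, generate_trial

scenario = SimScenario(
    clusters_per_stratum=24, cluster_size=30, icc=0.06, beta1=0.5, beta2=0.11
)
trial = generate_trial(scenario, np.random.default_rng(7))

results = analyze_all(trial)
table = pd.DataFrame([dataclasses.asdict(r) for r in results.values()])
cols = ["method", "estimate", "se", "df", "p_value", "ci_low", "ci_high"]
print(table[cols].round(4).to_string(index=False))

print(
    "\nAll four methods target the same treatment effect (true value 0.5)."
    "\nOn this balanced design the point estimates coincide exactly; the"
    "\nmethods differ only in their variance estimate and reference"
    "\ndistribution, which is what drives their small-sample differences."
)
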