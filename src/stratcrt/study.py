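"""Headline operating characteristics of the method-comparison study.

Bundles the two simulation campaigns the comparison rests on and the
cross-cluster-size aggregates reported for them:

* the null campaign (beta1 = 0, beta2 = 0.11) over the full grid of
  clusters-per-stratum {6, 24, 34, 68} x ICC {0.03, 0.06, 0.10} x the ten
  cluster sizes, which measures type I error;
* the low-effect campaign (beta1 = 0.11, beta2 = 0.11) over
  clusters-per-stratum {24, 34, 68}, which measures power and 95% CI
  coverage (the 6-cluster stratum is excluded because GEE and
  meta-regression do not hold their size there).

All headline values are percentages averaged over the ten cluster sizes
(and, where stated, over ICC values or methods whose reported behaviour is
common).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .harness import METHODS, GridConfig, cross_size_average, run_grid

NULL_J = (6, 24, 34, 68)
POWER_J = (24, 34, 68)
ICCS = (0.03, 0.06, 0.10)


def run_null_study(seed: int, n_reps: int = 1000) -> pd.DataFrame:
    """Type I error campaign: beta1 = 0, beta2 = 0.11, full J x ICC x size grid."""
    cfg = GridConfig(
        n_reps=n_reps,
        seed=seed,
        clusters_per_stratum=NULL_J,
        icc=ICCS,
        beta1=(0.0,),
        beta2=(0.11,),
    )
    return run_grid(cfg)


def run_power_study(seed: int, n_reps: int = 1000) -> pd.DataFrame:
    """Power/coverage campaign: beta1 = 0.11, beta2 = 0.11, J in {24, 34, 68}."""
    cfg = GridConfig(
        n_reps=n_reps,
        seed=seed,
        clusters_per_stratum=POWER_J,
        icc=ICCS,
        beta1=(0.11,),
        beta2=(0.11,),
    )
    return run_grid(cfg)


def size_average(
    table: pd.DataFrame,
    metric: str,
    method: str | tuple,
    j: int,
    icc: float | tuple,
) -> float:
    """Metric averaged over the ten cluster sizes (and any listed ICCs/methods)."""
    methods = (method,) if isinstance(method, str) else tuple(method)
    iccs = (icc,) if isinstance(icc, float) else tuple(icc)
    vals = [
        cross_size_average(
            table, metric, {"method": m, "clusters_per_stratum": j, "icc": rho}
        )
        for m in methods
        for rho in iccs
    ]
    return float(np.mean(vals))


def headline_summaries(
    null_table: pd.DataFrame, power_table: pd.DataFrame
) -> dict[str, float]:
    """The study's reported aggregates, as percentages."""
    out: dict[str, float] = {}
    # type I error, averaged over the three ICCs and ten sizes
    out["type1_gee_j6"] = 100 * size_average(
        null_table, "rejection_rate", "gee", 6, ICCS
    )
    out["type1_meta_j6"] = 100 * size_average(
        null_table, "rejection_rate", "meta_regression", 6, ICCS
    )
    out["type1_gee_meta_j24_j34"] = 100 * float(
        np.mean(
            [
                size_average(
                    null_table, "rejection_rate", ("gee", "meta_regression"), j, ICCS
                )
                for j in (24, 34)
            ]
        )
    )
    out["type1_gee_meta_j68"] = 100 * size_average(
        null_table, "rejection_rate", ("gee", "meta_regression"), 68, ICCS
    )
    lmm_cl = null_table[null_table["method"].isin(["lmm", "cl_regression"])]
    out["type1_lmm_cl_full_grid"] = 100 * float(lmm_cl["rejection_rate"].mean())

    # power at the low effect size
    out["power_gee_j24_icc03"] = 100 * size_average(
        power_table, "rejection_rate", "gee", 24, 0.03
    )
    out["power_gee_meta_j24_icc06"] = 100 * size_average(
        power_table, "rejection_rate", ("gee", "meta_regression"), 24, 0.06
    )
    out["power_lmm_cl_j24_icc06"] = 100 * size_average(
        power_table, "rejection_rate", ("lmm", "cl_regression"), 24, 0.06
    )
    for icc, tag in ((0.03, "03"), (0.06, "06"), (0.10, "10")):
        out[f"power_all_j68_icc{tag}"] = 100 * size_average(
            power_table, "rejection_rate", METHODS, 68, icc
        )

    # coverage of the 95% CI
    out["coverage_gee_meta_j24_icc06_10"] = 100 * size_average(
        power_table, "coverage", ("gee", "meta_regression"), 24, (0.06, 0.10)
    )
    out["coverage_min_j34_j68"] = 100 * min(
        np.mean(
            [size_average(power_table, "coverage", m, j, ICCS) for j in (34, 68)]
        )
        for m in METHODS
    )
    return out
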