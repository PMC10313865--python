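"""Cluster-summary analyses: stratum-adjusted OLS on cluster means, and
per-stratum mean differences pooled by fixed-effects inverse-variance
meta-analysis.

Both methods collapse each cluster to its mean outcome, which removes the
intra-cluster correlation from the error structure at the cost of modelling
one observation per cluster.  The regression route fits

    mean_y_g = b0 + b1 * arm_g + b2 * stratum_g + error_g

by OLS and tests b1 on K - 3 residual degrees of freedom (K clusters, three
estimated mean parameters).  The meta-analytic route computes, within each
stratum, the difference between the average treated-cluster mean and the
average control-cluster mean together with its two-sample variance, then
pools the per-stratum differences with inverse-variance weights under a
common-effect (fixed-effects) model and tests the pooled effect with a
z statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._design import DesignError, FitError
from .results import FitResult, t_inference, z_inference
from .simulate import validate_trial

__all__ = [
    "SUMMARY_COLUMNS",
    "StratumEffect",
    "cluster_means",
    "cl_linear_regression",
    "stratum_effects",
    "meta_fixed_effects",
    "analyze_cl_regression",
    "analyze_meta",
    "write_summary_csv",
    "read_summary_csv",
]

SUMMARY_COLUMNS = ("cluster_id", "stratum", "arm", "mean_y", "n_obs")


def cluster_means(data: pd.DataFrame) -> pd.DataFrame:
    """One row per cluster: stratum, arm, mean outcome and cluster size."""
    validate_trial(data)
    out = (
        data.groupby("cluster_id", sort=True)
        .agg(
            stratum=("stratum", "first"),
            arm=("arm", "first"),
            mean_y=("y", "mean"),
            n_obs=("y", "size"),
        )
        .reset_index()
    )
    return out


def cl_linear_regression(summary: pd.DataFrame) -> FitResult:
    """Stratum-adjusted OLS on cluster means with a t test for the arm effect.

    Residual degrees of freedom are K - 3 (clusters minus the three
    estimated mean parameters).
    """
    k = len(summary)
    if k < 5:
        raise DesignError("cluster-level regression needs at least 5 clusters")
    x = np.column_stack(
        [
            np.ones(k),
            summary["arm"].to_numpy(dtype=float),
            summary["stratum"].to_numpy(dtype=float),
        ]
    )
    if np.linalg.matrix_rank(x) < 3:
        raise DesignError("cluster-level design is rank deficient")
    y = summary["mean_y"].to_numpy(dtype=float)
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    df = k - 3
    s2 = float(resid @ resid) / df
    se = math.sqrt(s2 * xtx_inv[1, 1])
    return t_inference("cl_regression", float(beta[1]), se, df)


@dataclass(frozen=True)
class StratumEffect:
    """Arm difference of cluster-mean averages within one stratum."""

    stratum: int
    effect: float
    variance: float
    m_treat: int
    m_control: int


def stratum_effects(summary: pd.DataFrame) -> list[StratumEffect]:
    """Per-stratum treated-minus-control difference of cluster-mean averages.

    The variance is the two-sample formula s2_t/m_t + s2_c/m_c on cluster
    means (sample variances, denominator m - 1); it requires at least two
    clusters per arm within the stratum.
    """
    effects = []
    for s, grp in summary.groupby("stratum", sort=True):
        treat = grp.loc[grp["arm"] == 1, "mean_y"].to_numpy(dtype=float)
        ctrl = grp.loc[grp["arm"] == 0, "mean_y"].to_numpy(dtype=float)
        if len(treat) < 2 or len(ctrl) < 2:
            raise FitError(
                f"stratum {s}: need >=2 clusters per arm to estimate a variance"
            )
        effect = float(treat.mean() - ctrl.mean())
        variance = float(treat.var(ddof=1) / len(treat) + ctrl.var(ddof=1) / len(ctrl))
        effects.append(
            StratumEffect(
                stratum=int(s),
                effect=effect,
                variance=variance,
                m_treat=len(treat),
                m_control=len(ctrl),
            )
        )
    return effects


def meta_fixed_effects(effects: Sequence[StratumEffect]) -> FitResult:
    """Common-effect inverse-variance pooling of stratum effects, z test.

    pooled = sum(w_s * effect_s) / sum(w_s) with w_s = 1/variance_s and
    SE = sum(w_s)^(-1/2).  A non-positive stratum variance (degenerate data)
    is a pooling error, not an infinite weight.
    """
    if not effects:
        raise FitError("no stratum effects to pool")
    if any(e.variance <= 0 for e in effects):
        raise FitError("non-positive stratum variance: cannot pool")
    w = np.array([1.0 / e.variance for e in effects])
    est = np.array([e.effect for e in effects])
    pooled = float(np.sum(w * est) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return z_inference("meta_regression", pooled, se)


def analyze_cl_regression(data: pd.DataFrame) -> FitResult:
    """Convenience wrapper: cluster means + stratum-adjusted OLS t test."""
    return cl_linear_regression(cluster_means(data))


def analyze_meta(data: pd.DataFrame) -> FitResult:
    """Convenience wrapper: cluster means + fixed-effects pooled z test."""
    return meta_fixed_effects(stratum_effects(cluster_means(data)))


def write_summary_csv(summary: pd.DataFrame, path: str | Path) -> None:
    summary.loc[:, list(SUMMARY_COLUMNS)].to_csv(path, index=False)


def read_summary_csv(path: str | Path) -> pd.DataFrame:
    summary = pd.read_csv(path)
    missing = [c for c in SUMMARY_COLUMNS if c not in summary.columns]
    if missing:
        raise ValueError(f"cluster summary is missing columns {missing}")
    return summary
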