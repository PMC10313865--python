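"""Internal: per-cluster sufficient statistics for individual-level fitters.

Both the mixed model and the GEE operate on cluster-wise blocks whose
covariance is compound symmetric, so every quantity they need reduces to
per-cluster cross products of the design (intercept, arm, stratum), the
outcome, and the within-cluster sum vector.  Accumulating these once makes a
single fit O(K) in the number of clusters per criterion evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import validate_trial


class DesignError(ValueError):
    """The fixed-effects design is unusable (rank deficient, single arm...)."""


class FitError(RuntimeError):
    """Estimation failed (degenerate data, singular information)."""


@dataclass
class ClusterStats:
    """Per-cluster sufficient statistics; arrays indexed by cluster."""

    n: np.ndarray          # (K,) cluster sizes
    xtx: np.ndarray        # (K, p, p) X_g' X_g
    xt1: np.ndarray        # (K, p) X_g' 1
    xty: np.ndarray        # (K, p) X_g' y_g
    sty: np.ndarray        # (K,) 1' y_g
    yty: np.ndarray        # (K,) y_g' y_g

    @property
    def n_total(self) -> int:
        return int(self.n.sum())

    @property
    def n_clusters(self) -> int:
        return len(self.n)

    @property
    def p(self) -> int:
        return self.xtx.shape[1]


def design_matrix(data: pd.DataFrame) -> np.ndarray:
    """N x 3 fixed-effects design: intercept, treatment arm, stratum."""
    return np.column_stack(
        [
            np.ones(len(data)),
            data["arm"].to_numpy(dtype=float),
            data["stratum"].to_numpy(dtype=float),
        ]
    )


def cluster_stats(data: pd.DataFrame, min_clusters_per_arm: int = 2) -> ClusterStats:
    """Validate the trial and accumulate per-cluster cross products."""
    data = validate_trial(data)
    x = design_matrix(data)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DesignError("design matrix (intercept, arm, stratum) is rank deficient")
    arms = data.groupby("cluster_id")["arm"].first()
    if (arms == 1).sum() < min_clusters_per_arm or (arms == 0).sum() < min_clusters_per_arm:
        raise DesignError(f"need at least {min_clusters_per_arm} clusters in each arm")
    y = data["y"].to_numpy(dtype=float)
    codes, _ = pd.factorize(data["cluster_id"].to_numpy(), sort=True)
    k = codes.max() + 1
    n = np.bincount(codes, minlength=k).astype(float)
    p = x.shape[1]
    xtx = np.zeros((k, p, p))
    for a in range(p):
        for b in range(a, p):
            s = np.bincount(codes, weights=x[:, a] * x[:, b], minlength=k)
            xtx[:, a, b] = s
            xtx[:, b, a] = s
    xt1 = np.column_stack([np.bincount(codes, weights=x[:, a], minlength=k) for a in range(p)])
    xty = np.column_stack(
        [np.bincount(codes, weights=x[:, a] * y, minlength=k) for a in range(p)]
    )
    sty = np.bincount(codes, weights=y, minlength=k)
    yty = np.bincount(codes, weights=y * y, minlength=k)
    return ClusterStats(n=n, xtx=xtx, xt1=xt1, xty=xty, sty=sty, yty=yty)


def ols_fit(stats: ClusterStats) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS on the pooled individual-level data from the sufficient statistics.

    Returns (beta_hat, (X'X)^-1, residual sum of squares).
    """
    xtx = stats.xtx.sum(axis=0)
    xty = stats.xty.sum(axis=0)
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ xty
    rss = float(stats.yty.sum() - beta @ xty)
    return beta, xtx_inv, rss
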