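"""Population-averaged linear model via generalized estimating equations.

Identity link, Gaussian variance function, exchangeable working correlation:
within a cluster all pairs share one working correlation alpha.  The
coefficients solve

    sum_g X_g' V_g^-1 (y_g - X_g beta) = 0,
    V_g = phi * [(1 - alpha) I + alpha J]

with alpha and phi refreshed from moment estimators at each iteration.
Inference uses the Liang-Zeger sandwich (robust) covariance, which is
consistent under working-correlation misspecification but is known to
understate the sampling variance when the number of clusters is small —
no small-sample correction is applied, by design, because the plain
sandwich is the estimator whose operating characteristics this package
studies.  The treatment effect is tested by the 1-df chi-square Wald
statistic; the 95% CI is Wald normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._design import ClusterStats, DesignError, FitError, cluster_stats, ols_fit
from .results import FitResult, Z_975

__all__ = ["GEEFit", "gee_fit", "gee_test", "analyze_gee", "DesignError", "FitError"]


@dataclass
class GEEFit:
    """Converged GEE solution for (intercept, arm, stratum)."""

    beta_hat: np.ndarray
    alpha_hat: float
    phi_hat: float
    robust_cov: np.ndarray
    model_cov: np.ndarray
    n_iter: int
    converged: bool


def _moment_alpha_phi(stats: ClusterStats, beta: np.ndarray) -> tuple[float, float]:
    """Moment estimators of the working correlation and the scale.

    phi = sum r^2 / (N - p); alpha pools within-cluster residual cross
    products over sum n_g(n_g - 1)/2 - p pairs (the parameter-count
    correction of standard GEE software).
    """
    n_tot, p = stats.n_total, stats.p
    # per-cluster residual summaries from sufficient statistics
    rss = stats.yty - 2 * np.einsum("kp,p->k", stats.xty, beta) + np.einsum(
        "kpq,p,q->k", stats.xtx, beta, beta
    )
    rsum = stats.sty - stats.xt1 @ beta
    phi = float(rss.sum() / (n_tot - p))
    cross = 0.5 * float(np.sum(rsum**2 - rss))  # sum over i<i' of r_i r_i'
    pairs = float(np.sum(stats.n * (stats.n - 1) / 2.0))
    denom = pairs - p
    if denom <= 0:
        return 0.0, phi  # alpha inestimable (e.g. all clusters of size 1)
    return cross / phi / denom, phi


def _working_info(stats: ClusterStats, alpha: float):
    """Bread and X'V^-1 y under the exchangeable working covariance (phi = 1).

    V^-1 = (1/(1-alpha)) [I - c J],  c = alpha / (1 - alpha + n*alpha).
    """
    c = alpha / (1.0 - alpha + stats.n * alpha)
    scale = 1.0 / (1.0 - alpha)
    a = scale * (
        stats.xtx.sum(axis=0) - np.einsum("k,ki,kj->ij", c, stats.xt1, stats.xt1)
    )
    b = scale * (stats.xty.sum(axis=0) - stats.xt1.T @ (c * stats.sty))
    return a, b, c, scale


def gee_fit(data: pd.DataFrame, max_iter: int = 100, tol: float = 1e-8) -> GEEFit:
    """Fit the exchangeable-correlation GEE by Fisher scoring.

    Alternates the GLS-type coefficient update with the moment update of
    (alpha, phi) until the maximum absolute coefficient change falls below
    ``tol``.  Raises on rank-deficient designs; flags (rather than raises)
    non-convergence.
    """
    stats = cluster_stats(data, min_clusters_per_arm=1)
    if stats.n_clusters < 2:
        raise DesignError("GEE requires at least two clusters")
    beta, _, _ = ols_fit(stats)
    alpha = 0.0
    n_max = float(stats.n.max())
    alpha_lo = -1.0 / (n_max - 1.0) + 1e-8 if n_max > 1 else 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        alpha, phi = _moment_alpha_phi(stats, beta)
        alpha = float(np.clip(alpha, alpha_lo, 1.0 - 1e-8))
        a, b, _, _ = _working_info(stats, alpha)
        try:
            beta_new = np.linalg.solve(a, b)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular working covariance") from exc
        delta = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        if delta < tol:
            converged = True
            break
    alpha, phi = _moment_alpha_phi(stats, beta)
    alpha = float(np.clip(alpha, alpha_lo, 1.0 - 1e-8))
    a, _, c, scale = _working_info(stats, alpha)
    bread = np.linalg.inv(a)

    # meat: sum_g X_g' V_g^-1 r_g r_g' V_g^-1 X_g with phi cancelling
    rsum = stats.sty - stats.xt1 @ beta  # (K,)
    # X_g' V^-1 r_g = scale * (X_g'r_g - c * (1'r_g) X_g'1)
    xtr = stats.xty - np.einsum("kpq,q->kp", stats.xtx, beta)  # (K, p)
    u = scale * (xtr - (c * rsum)[:, None] * stats.xt1)  # (K, p)
    meat = u.T @ u
    robust_cov = bread @ meat @ bread
    model_cov = phi * bread
    return GEEFit(
        beta_hat=beta,
        alpha_hat=alpha,
        phi_hat=phi,
        robust_cov=robust_cov,
        model_cov=model_cov,
        n_iter=it,
        converged=converged,
    )


def gee_test(fit: GEEFit) -> FitResult:
    """1-df chi-square Wald test of the treatment effect, sandwich variance.

    The 95% CI is Wald normal (estimate +/- 1.96 * robust SE), consistent
    with the chi-square test through the z^2 identity.
    """
    if not fit.converged:
        raise FitError("cannot test a non-converged fit")
    var = float(fit.robust_cov[1, 1])
    if var <= 0:
        raise FitError("zero robust variance for the treatment effect")
    est = float(fit.beta_hat[1])
    se = math.sqrt(var)
    stat = est * est / var
    p = float(sps.chi2.sf(stat, 1))
    half = Z_975 * se
    return FitResult(
        "gee", est, se, math.inf, stat, p, est - half, est + half
    )


def analyze_gee(data: pd.DataFrame) -> FitResult:
    """Convenience wrapper: GEE fit + chi-square Wald test."""
    return gee_test(gee_fit(data))
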