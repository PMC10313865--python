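"""Random-intercept linear mixed model fitted by REML.

The model for individual i in cluster j is

    y_ij = x_ij' beta + C_j + e_ij,   C_j ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_e^2)

with fixed effects (intercept, treatment arm, stratum).  The per-cluster
covariance is compound symmetric, so everything is computed from per-cluster
sufficient statistics via the Woodbury identity — the N x N covariance is
never formed and the cost per REML evaluation is O(K) in the number of
clusters.

Estimation profiles the fixed effects and the residual variance out of the
REML criterion, leaving a one-dimensional optimization over the variance
ratio lambda = sigma_b^2 / sigma_e^2 with an explicit boundary check at
lambda = 0.  The treatment-effect t test uses Satterthwaite degrees of
freedom computed from the gradient of the coefficient variance with respect
to (sigma_b^2, sigma_e^2) and the inverse curvature of the REML criterion —
the convention of standard small-sample mixed-model inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from ._design import ClusterStats, DesignError, FitError, cluster_stats
from .results import FitResult, t_inference

__all__ = [
    "LMMFit",
    "reml_fit",
    "reml_neg2loglik",
    "satterthwaite_df",
    "lmm_test",
    "analyze_lmm",
    "DesignError",
    "FitError",
]

_LOG2PI = math.log(2.0 * math.pi)


def _gls_pieces(stats: ClusterStats, lam: float):
    """A(lam) = sigma_e^2 * X'V^-1 X, b(lam) = sigma_e^2 * X'V^-1 y, Q(lam).

    Uses (I + lam*J)^-1 = I - (lam / (1 + n*lam)) J per cluster; Q is the GLS
    residual quadratic form scaled by sigma_e^2.
    """
    w = lam / (1.0 + stats.n * lam)  # (K,)
    a = stats.xtx.sum(axis=0) - np.einsum("k,ki,kj->ij", w, stats.xt1, stats.xt1)
    b = stats.xty.sum(axis=0) - stats.xt1.T @ (w * stats.sty)
    yty_w = float(stats.yty.sum() - np.sum(w * stats.sty**2))
    beta = np.linalg.solve(a, b)
    q = yty_w - float(beta @ b)
    return a, b, beta, q


def _profile_neg2_reml(stats: ClusterStats, lam: float) -> float:
    """-2 * restricted log-likelihood profiled over beta and sigma_e^2."""
    n_tot, p = stats.n_total, stats.p
    a, _, _, q = _gls_pieces(stats, lam)
    if q <= 0:
        raise FitError("degenerate data: zero residual variation")
    sig_e2 = q / (n_tot - p)
    logdet_v = float(np.sum(np.log1p(stats.n * lam)))
    sign, logdet_a = np.linalg.slogdet(a)
    if sign <= 0:
        raise FitError("singular GLS information")
    return (n_tot - p) * (math.log(sig_e2) + 1.0 + _LOG2PI) + logdet_v + logdet_a


def reml_neg2loglik(data_or_stats, sigma_b2: float, sigma_e2: float) -> float:
    """-2 * restricted log-likelihood at explicit variance components.

    Exposed so the attained criterion can be checked against grid searches;
    equals ``-2 * reml_loglik`` of :func:`reml_fit` at the estimates.
    """
    stats = (
        data_or_stats
        if isinstance(data_or_stats, ClusterStats)
        else cluster_stats(data_or_stats)
    )
    if sigma_e2 <= 0 or sigma_b2 < 0:
        return math.inf
    lam = sigma_b2 / sigma_e2
    n_tot, p = stats.n_total, stats.p
    a, _, _, q = _gls_pieces(stats, lam)
    logdet_v = n_tot * math.log(sigma_e2) + float(np.sum(np.log1p(stats.n * lam)))
    sign, logdet_a = np.linalg.slogdet(a)
    if sign <= 0:
        return math.inf
    logdet_info = logdet_a - p * math.log(sigma_e2)
    return logdet_v + logdet_info + q / sigma_e2 + (n_tot - p) * _LOG2PI


@dataclass
class LMMFit:
    """REML fit of the random-intercept model.

    ``cov_beta`` is the fixed-effects covariance at the estimated variance
    components; ``vc_cov`` the asymptotic covariance of (sigma_b2, sigma_e2)
    from the inverse curvature of the REML criterion (None at the
    sigma_b2 = 0 boundary, where that curvature is invalid).
    """

    beta_hat: np.ndarray
    sigma_b2: float
    sigma_e2: float
    cov_beta: np.ndarray
    reml_loglik: float
    vc_cov: np.ndarray | None
    converged: bool
    boundary: bool
    _stats: ClusterStats = field(repr=False)

    @property
    def icc_hat(self) -> float:
        return self.sigma_b2 / (self.sigma_b2 + self.sigma_e2)


_LOG_LAM_LO, _LOG_LAM_HI = -25.0, 14.0  # lambda from ~1.4e-11 to ~1.2e6


def reml_fit(data: pd.DataFrame) -> LMMFit:
    """Fit the random-intercept model by REML.

    Optimizes the profiled criterion over log(lambda) by bounded scalar
    minimization and compares against the lambda = 0 boundary; the boundary
    fit coincides with OLS on the same design.
    """
    stats = cluster_stats(data)
    n_tot, p = stats.n_total, stats.p

    obj = lambda t: _profile_neg2_reml(stats, math.exp(t))
    res = optimize.minimize_scalar(
        obj,
        bounds=(_LOG_LAM_LO, _LOG_LAM_HI),
        method="bounded",
        options={"xatol": 1e-10},
    )
    crit0 = _profile_neg2_reml(stats, 0.0)
    boundary = crit0 <= res.fun + 1e-10
    lam = 0.0 if boundary else math.exp(res.x)
    crit = crit0 if boundary else float(res.fun)
    converged = bool(res.success) or boundary

    a, _, beta, q = _gls_pieces(stats, lam)
    sigma_e2 = q / (n_tot - p)
    sigma_b2 = lam * sigma_e2
    cov_beta = sigma_e2 * np.linalg.inv(a)

    vc_cov = None if boundary else _vc_covariance(stats, sigma_b2, sigma_e2)
    return LMMFit(
        beta_hat=beta,
        sigma_b2=sigma_b2,
        sigma_e2=sigma_e2,
        cov_beta=cov_beta,
        reml_loglik=-0.5 * crit,
        vc_cov=vc_cov,
        converged=converged,
        boundary=boundary,
        _stats=stats,
    )


def _vc_covariance(
    stats: ClusterStats, sigma_b2: float, sigma_e2: float
) -> np.ndarray | None:
    """2 * inverse Hessian of -2*logLik_REML in (sigma_b2, sigma_e2).

    Central finite differences.  The step is 1e-3 relative, floored at 5% of
    the total variance: second differences lose half the working precision,
    so a step sized for first derivatives would drown the curvature in
    rounding noise near the sigma_b2 = 0 boundary.
    """
    theta = np.array([sigma_b2, sigma_e2])
    h = 1e-3 * np.maximum(np.abs(theta), 0.05 * theta.sum())
    hess = np.empty((2, 2))
    f = lambda t: reml_neg2loglik(stats, t[0], t[1])
    f0 = f(theta)
    for i in range(2):
        ei = np.zeros(2)
        ei[i] = h[i]
        hess[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
    e0 = np.array([h[0], 0.0])
    e1 = np.array([0.0, h[1]])
    hess[0, 1] = hess[1, 0] = (
        f(theta + e0 + e1) - f(theta + e0 - e1) - f(theta - e0 + e1) + f(theta - e0 - e1)
    ) / (4 * h[0] * h[1])
    try:
        return 2.0 * np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return None


def _var_beta1_gradient(
    stats: ClusterStats, sigma_b2: float, sigma_e2: float
) -> tuple[np.ndarray, float]:
    """Analytic gradient of Var(beta1_hat) in (sigma_b2, sigma_e2).

    With Phi = (X'V^-1 X)^-1,  dPhi/dtheta_i = Phi X'V^-1 (dV/dtheta_i) V^-1 X Phi,
    where dV/dsigma_b2 is block-diagonal J and dV/dsigma_e2 = I; both contract
    against the per-cluster sufficient statistics through the Woodbury form
    of V^-1.
    """
    lam = sigma_b2 / sigma_e2
    a, *_ = _gls_pieces(stats, lam)
    phi = sigma_e2 * np.linalg.inv(a)
    # 1'V_g^-1 = 1' / (sigma_e2 (1 + n lam))
    d = (sigma_e2 * (1.0 + stats.n * lam)) ** -2
    m_b = np.einsum("k,ki,kj->ij", d, stats.xt1, stats.xt1)
    w = lam / (1.0 + stats.n * lam)
    coef = (w * w * stats.n - 2.0 * w) / sigma_e2**2
    m_e = stats.xtx.sum(axis=0) / sigma_e2**2 + np.einsum(
        "k,ki,kj->ij", coef, stats.xt1, stats.xt1
    )
    grad = np.array([(phi @ m_b @ phi)[1, 1], (phi @ m_e @ phi)[1, 1]])
    return grad, float(phi[1, 1])


def satterthwaite_df(fit: LMMFit) -> float:
    """Satterthwaite degrees of freedom for the treatment-effect t test.

    nu = 2 * v^2 / (g' A g) with v the estimated variance of the treatment
    coefficient, g its (analytic) gradient in (sigma_b2, sigma_e2), and A the
    asymptotic covariance of the variance components.  At the sigma_b2 = 0
    boundary the curvature-based formula is invalid and the OLS residual df
    (N - p) is returned instead.
    """
    stats = fit._stats
    if fit.boundary or fit.vc_cov is None:
        return float(stats.n_total - stats.p)
    grad, _ = _var_beta1_gradient(stats, fit.sigma_b2, fit.sigma_e2)
    v = float(fit.cov_beta[1, 1])
    denom = float(grad @ fit.vc_cov @ grad)
    if denom <= 0:
        raise FitError("Satterthwaite denominator non-positive: singular information")
    return 2.0 * v * v / denom


def lmm_test(fit: LMMFit) -> FitResult:
    """t test of the treatment effect with Satterthwaite df."""
    if not fit.converged:
        raise FitError("cannot test a non-converged fit")
    se = math.sqrt(fit.cov_beta[1, 1])
    return t_inference("lmm", float(fit.beta_hat[1]), se, satterthwaite_df(fit))


def analyze_lmm(data: pd.DataFrame) -> FitResult:
    """Convenience wrapper: REML fit + Satterthwaite t test."""
    return lmm_test(reml_fit(data))
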