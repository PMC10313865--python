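"""Shared container for one method's inference on one trial."""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

Z_975 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass(frozen=True)
class FitResult:
    """Treatment-effect inference from a single analysis method.

    ``df`` is the degrees of freedom of the reference t distribution, or
    ``math.inf`` for normal/chi-square based methods.
    """

    method: str
    estimate: float
    se: float
    df: float
    statistic: float
    p_value: float
    ci_low: float
    ci_high: float
    converged: bool = True

    @property
    def ci_width(self) -> float:
        return self.ci_high - self.ci_low

    def covers(self, true_value: float) -> bool:
        return self.ci_low <= true_value <= self.ci_high

    def rejects(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def t_inference(method: str, estimate: float, se: float, df: float) -> FitResult:
    """Two-sided t test and 95% CI for a treatment effect."""
    stat = estimate / se
    p = 2.0 * stats.t.sf(abs(stat), df)
    half = stats.t.ppf(0.975, df) * se
    return FitResult(method, estimate, se, df, stat, p, estimate - half, estimate + half)


def z_inference(method: str, estimate: float, se: float) -> FitResult:
    """Two-sided z (equivalently 1-df chi-square) test and Wald 95% CI."""
    stat = estimate / se
    p = 2.0 * stats.norm.sf(abs(stat))
    half = Z_975 * se
    return FitResult(
        method, estimate, se, math.inf, stat, p, estimate - half, estimate + half
    )


def failed_result(method: str) -> FitResult:
    """Placeholder for a fit that did not converge; excluded from metrics."""
    nan = float("nan")
    return FitResult(method, nan, nan, nan, nan, nan, nan, nan, converged=False)
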