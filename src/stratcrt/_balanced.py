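"""Internal: closed-form analyses for balanced generated trials.

For the study's designs — equal cluster sizes, cluster-level covariates,
1:1 allocation within stratum — all four methods are functions of two
sufficient statistics per trial: the vector of cluster means and the pooled
within-cluster sum of squares.  In particular:

* the GLS / GEE / OLS point estimate of (intercept, arm, stratum) equals the
  OLS fit on cluster means, whatever the working correlation or variance
  ratio, so no iteration is needed;
* REML has a closed form: sigma_e^2 = SSW / (N - K) and the cluster-mean
  residual mean square estimates tau = sigma_b^2 + sigma_e^2 / n on K - 3
  degrees of freedom (with an explicit boundary fit, equal to pooled OLS,
  when the implied sigma_b^2 is negative).  The Satterthwaite df of the
  treatment t statistic then collapses to exactly K - 3 in the interior;
* the Liang-Zeger sandwich reduces to the HC0 form on cluster means — the
  working alpha and scale cancel.

These identities let a whole replicate batch be analyzed with a handful of
matrix products.  The general per-dataset fitters in ``lmm``/``gee``/
``cluster_level`` remain the reference implementations; the test suite pins
this engine to them replicate by replicate.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .results import Z_975
from .simulate import SimScenario, cluster_design, _draw_effects

METHODS = ("lmm", "gee", "cl_regression", "meta_regression")


class BalancedCell:
    """Precomputed design quantities for one scenario cell."""

    def __init__(self, scenario: SimScenario):
        self.scenario = scenario
        design = cluster_design(scenario)
        self.k = scenario.n_clusters
        self.n = scenario.cluster_size
        self.n_total = scenario.n_individuals
        self.x = np.column_stack(
            [
                np.ones(self.k),
                design["arm"].to_numpy(dtype=float),
                design["stratum"].to_numpy(dtype=float),
            ]
        )
        xtx_inv = np.linalg.inv(self.x.T @ self.x)
        self.proj = xtx_inv @ self.x.T       # (3, K): beta = proj @ means
        self.a11 = float(xtx_inv[1, 1])
        self.cell_mean = (
            scenario.beta0
            + scenario.beta1 * self.x[:, 1]
            + scenario.beta2 * self.x[:, 2]
        )
        # index sets for the meta-analytic route
        s = design["stratum"].to_numpy()
        a = design["arm"].to_numpy()
        self.groups = {
            (int(ss), int(aa)): np.flatnonzero((s == ss) & (a == aa))
            for ss in (0, 1)
            for aa in (0, 1)
        }

    def simulate_batch(
        self, seed_seqs: list[np.random.SeedSequence]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Cluster means (R, K) and within-cluster SS (R,) for R replicates.

        Each replicate consumes its own substream in the same draw order as
        :func:`stratcrt.simulate.generate_trial`, so replicate r here is the
        same trial that ``generate_trial(scenario, default_rng(seed_seqs[r]))``
        would return.
        """
        r = len(seed_seqs)
        means = np.empty((r, self.k))
        ssw = np.empty(r)
        for i, ss in enumerate(seed_seqs):
            rng = np.random.default_rng(ss)
            c, e = _draw_effects(self.scenario, rng)
            ebar = e.mean(axis=1)
            means[i] = self.cell_mean + c + ebar
            ssw[i] = float(np.sum(e * e) - self.n * np.sum(ebar * ebar))
        return means, ssw

    def analyze_batch(self, means: np.ndarray, ssw: np.ndarray) -> dict:
        """All four methods on a batch; dict method -> arrays.

        Each entry holds ``estimate``, ``p_value``, ``ci_low``, ``ci_high``,
        ``se`` and ``converged`` of shape (R,).
        """
        k, n, n_tot, a11 = self.k, self.n, self.n_total, self.a11
        beta = means @ self.proj.T                 # (R, 3)
        est = beta[:, 1]
        resid = means - beta @ self.x.T            # (R, K)
        ssb = np.einsum("rk,rk->r", resid, resid)
        out: dict[str, dict[str, np.ndarray]] = {}

        # cluster-level OLS: residual mean square on K - 3 df
        df_cl = k - 3
        var_cl = ssb / df_cl * a11
        out["cl_regression"] = _t_arrays(est, np.sqrt(var_cl), df_cl)

        # REML mixed model with Satterthwaite df (= K - 3 in the interior)
        sigma_e2 = ssw / (n_tot - k)
        tau = ssb / df_cl
        interior = tau > sigma_e2 / n
        var_lmm = np.where(
            interior, tau * a11, (ssw + n * ssb) / (n_tot - 3) * a11 / n
        )
        df_lmm = np.where(interior, float(df_cl), float(n_tot - 3))
        out["lmm"] = _t_arrays(est, np.sqrt(var_lmm), df_lmm)

        # GEE sandwich: HC0 on cluster means
        h2 = self.proj[1] ** 2                     # (K,)
        var_gee = (resid * resid) @ h2
        se_gee = np.sqrt(var_gee)
        stat = est * est / var_gee
        out["gee"] = {
            "estimate": est,
            "se": se_gee,
            "p_value": sps.chi2.sf(stat, 1),
            "ci_low": est - Z_975 * se_gee,
            "ci_high": est + Z_975 * se_gee,
            "converged": np.ones(len(est), dtype=bool),
        }

        # fixed-effects meta-analysis of per-stratum arm differences
        eff = {}
        var = {}
        for s in (0, 1):
            parts = {}
            for a in (0, 1):
                idx = self.groups[(s, a)]
                sub = means[:, idx]
                mu = sub.mean(axis=1)
                v = sub.var(axis=1, ddof=1) / len(idx)
                parts[a] = (mu, v)
            eff[s] = parts[1][0] - parts[0][0]
            var[s] = parts[1][1] + parts[0][1]
        w0, w1 = 1.0 / var[0], 1.0 / var[1]
        pooled = (w0 * eff[0] + w1 * eff[1]) / (w0 + w1)
        se_meta = (w0 + w1) ** -0.5
        zstat = pooled / se_meta
        out["meta_regression"] = {
            "estimate": pooled,
            "se": se_meta,
            "p_value": 2.0 * sps.norm.sf(np.abs(zstat)),
            "ci_low": pooled - Z_975 * se_meta,
            "ci_high": pooled + Z_975 * se_meta,
            "converged": np.ones(len(est), dtype=bool),
        }
        return out


def _t_arrays(est: np.ndarray, se: np.ndarray, df) -> dict[str, np.ndarray]:
    df = np.broadcast_to(np.asarray(df, dtype=float), est.shape)
    stat = est / se
    half = sps.t.ppf(0.975, df) * se
    return {
        "estimate": est,
        "se": se,
        "p_value": 2.0 * sps.t.sf(np.abs(stat), df),
        "ci_low": est - half,
        "ci_high": est + half,
        "converged": np.ones(len(est), dtype=bool),
    }
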