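"""Cluster-summary methods: OLS on cluster means and fixed-effects pooling."""

import numpy as np
import pandas as pd
import pytest

from stratcrt import (
    SimScenario,
    StratumEffect,
    cl_linear_regression,
    cluster_means,
    generate_trial,
    meta_fixed_effects,
    stratum_effects,
)
from stratcrt.cluster_level import (
    DesignError,
    FitError,
    read_summary_csv,
    write_summary_csv,
)


def summary_frame(means, strata, arms):
    return pd.DataFrame(
        {
            "cluster_id": np.arange(len(means)),
            "stratum": strata,
            "arm": arms,
            "mean_y": means,
            "n_obs": 4,
        }
    )


EIGHT_CLUSTER_MEANS = summary_frame(
    [1.0, 1.2, 1.5, 1.7, 2.0, 2.2, 2.6, 2.8],
    [0, 0, 0, 0, 1, 1, 1, 1],
    [0, 0, 1, 1, 0, 0, 1, 1],
)


def test_cluster_means_basic():
    data = pd.DataFrame(
        {
            "cluster_id": [1, 1, 1, 2, 2, 2],
            "stratum": [0, 0, 0, 1, 1, 1],
            "arm": [0, 0, 0, 1, 1, 1],
            "y": [1.0, 2.0, 3.0, 5.0, 5.0, 5.0],
        }
    )
    summary = cluster_means(data)
    assert list(summary["mean_y"]) == [2.0, 5.0]
    assert list(summary["n_obs"]) == [3, 3]
    assert summary["n_obs"].sum() == len(data)


def test_cluster_means_counts_for_smallest_grid_cell():
    scen = SimScenario(6, 5, 0.03, 0.0, 0.11)
    summary = cluster_means(generate_trial(scen, np.random.default_rng(2)))
    assert len(summary) == 12
    assert (summary["n_obs"] == 5).all()


def test_cluster_means_constant_outcome():
    data = pd.DataFrame(
        {
            "cluster_id": np.repeat([0, 1, 2, 3], 3),
            "stratum": np.repeat([0, 0, 1, 1], 3),
            "arm": np.repeat([0, 1, 0, 1], 3),
            "y": 4.2,
        }
    )
    assert (cluster_means(data)["mean_y"] == 4.2).all()


class TestClusterLevelRegression:
    def test_matches_normal_equations(self):
        """Closed-form OLS oracle on the 8-cluster summary, machine precision."""
        x = np.column_stack(
            [
                np.ones(8),
                EIGHT_CLUSTER_MEANS["arm"].to_numpy(float),
                EIGHT_CLUSTER_MEANS["stratum"].to_numpy(float),
            ]
        )
        y = EIGHT_CLUSTER_MEANS["mean_y"].to_numpy()
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        result = cl_linear_regression(EIGHT_CLUSTER_MEANS)
        assert result.estimate == pytest.approx(beta[1], abs=1e-14)
        resid = y - x @ beta
        s2 = resid @ resid / (8 - 3)
        se = np.sqrt(s2 * np.linalg.inv(x.T @ x)[1, 1])
        assert result.se == pytest.approx(se, abs=1e-14)
        assert result.df == 5  # K - 3

    def test_exact_fit_recovers_shift_with_zero_residual(self):
        # treated means exceed control by exactly 0.7 in both strata
        means = summary_frame(
            [1.0, 1.0, 1.7, 1.7, 3.0, 3.0, 3.7, 3.7],
            [0, 0, 0, 0, 1, 1, 1, 1],
            [0, 0, 1, 1, 0, 0, 1, 1],
        )
        result = cl_linear_regression(means)
        assert result.estimate == pytest.approx(0.7, abs=1e-12)
        assert result.se == pytest.approx(0.0, abs=1e-12)

    def test_frisch_waugh_degenerate_case(self):
        """Stratum balanced across arms: estimate equals simple arm difference."""
        rng = np.random.default_rng(31)
        means = summary_frame(
            rng.standard_normal(12),
            [0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1],
            [0, 0, 0, 1, 1, 1, 0, 0, 0, 1, 1, 1],
        )
        result = cl_linear_regression(means)
        diff = (
            means.loc[means["arm"] == 1, "mean_y"].mean()
            - means.loc[means["arm"] == 0, "mean_y"].mean()
        )
        assert result.estimate == pytest.approx(diff, abs=1e-12)

    def test_too_few_clusters_rejected(self):
        with pytest.raises(DesignError):
            cl_linear_regression(EIGHT_CLUSTER_MEANS.head(4))


class TestStratumEffects:
    def test_hand_computed_effect_and_variance(self):
        means = summary_frame([1.0, 3.0, 2.0, 4.0], [0, 0, 0, 0], [0, 0, 1, 1])
        (eff,) = stratum_effects(means)
        assert eff.effect == pytest.approx(1.0)
        assert eff.variance == pytest.approx(2.0)  # 2/2 + 2/2
        assert (eff.m_treat, eff.m_control) == (2, 2)

    def test_degenerate_equal_means_flagged_on_pooling(self):
        means = summary_frame([1.0, 1.0, 1.0, 1.0], [0, 0, 0, 0], [0, 0, 1, 1])
        (eff,) = stratum_effects(means)
        assert eff.effect == 0.0
        assert eff.variance == 0.0
        with pytest.raises(FitError):
            meta_fixed_effects([eff])

    def test_requires_two_clusters_per_arm(self):
        means = summary_frame([1.0, 2.0, 3.0], [0, 0, 0], [0, 1, 1])
        with pytest.raises(FitError):
            stratum_effects(means)

    def test_consistency_on_large_synthetic_trial(self):
        scen = SimScenario(400, 10, 0.06, 0.11, 0.5)
        data = generate_trial(scen, np.random.default_rng(6))
        for eff in stratum_effects(cluster_means(data)):
            assert eff.effect == pytest.approx(0.11, abs=4 * np.sqrt(eff.variance))


class TestMetaFixedEffects:
    def test_equal_effects_pool_to_themselves(self):
        effs = [StratumEffect(0, 1.0, 2.0, 2, 2), StratumEffect(1, 1.0, 2.0, 2, 2)]
        result = meta_fixed_effects(effs)
        assert result.estimate == pytest.approx(1.0)
        assert result.se == pytest.approx(1.0)

    def test_hand_computed_inverse_variance_pooling(self):
        effs = [StratumEffect(0, 2.0, 1.0, 3, 3), StratumEffect(1, 0.0, 3.0, 3, 3)]
        result = meta_fixed_effects(effs)
        assert result.estimate == pytest.approx(1.5)
        assert result.se == pytest.approx((4.0 / 3.0) ** -0.5)
        assert result.se == pytest.approx(0.8660, abs=5e-5)

    def test_single_stratum_identity(self):
        (r,) = [meta_fixed_effects([StratumEffect(0, 0.4, 0.09, 5, 5)])]
        assert r.estimate == pytest.approx(0.4)
        assert r.se == pytest.approx(0.3)

    def test_order_invariance_and_scale_equivariance(self):
        effs = [StratumEffect(0, 2.0, 1.0, 3, 3), StratumEffect(1, 0.5, 3.0, 3, 3)]
        a = meta_fixed_effects(effs)
        b = meta_fixed_effects(list(reversed(effs)))
        assert a.estimate == b.estimate and a.se == b.se
        scaled = [
            StratumEffect(e.stratum, 10 * e.effect, 100 * e.variance, 3, 3)
            for e in effs
        ]
        c = meta_fixed_effects(scaled)
        assert c.estimate == pytest.approx(10 * a.estimate)
        assert c.se == pytest.approx(10 * a.se)


def test_summary_csv_roundtrip(tmp_path):
    path = tmp_path / "summary.csv"
    write_summary_csv(EIGHT_CLUSTER_MEANS, path)
    back = read_summary_csv(path)
    pd.testing.assert_frame_equal(back, EIGHT_CLUSTER_MEANS)
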