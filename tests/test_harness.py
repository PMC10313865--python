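"""Monte Carlo harness: determinism, metrics, engines, aggregation."""

import math

import numpy as np
import pandas as pd
import pytest

from stratcrt import (
    METHODS,
    FitResult,
    GridConfig,
    SimScenario,
    analyze_all,
    cross_size_average,
    run_grid,
    run_replicate,
    summarize,
)
from stratcrt.harness import cell_seed_sequence, run_cell


def test_run_replicate_is_deterministic():
    scen = SimScenario(6, 5, 0.06, 0.11, 0.5)
    a = run_replicate(scen, np.random.default_rng(4))
    b = run_replicate(scen, np.random.default_rng(4))
    assert a == b
    assert set(a) == set(METHODS)


def test_zero_icc_methods_collapse_to_ols_limit():
    scen = SimScenario(10, 8, 0.0, 0.11, 0.5)
    res = run_replicate(scen, np.random.default_rng(12))
    # with equal cluster sizes the individual-level and cluster-mean OLS
    # estimates coincide, so all point estimates should be within noise
    assert res["lmm"].estimate == pytest.approx(res["cl_regression"].estimate, abs=1e-8)
    assert res["gee"].estimate == pytest.approx(res["cl_regression"].estimate, abs=1e-8)


def test_cross_method_estimates_agree_within_sampling_noise():
    scen = SimScenario(24, 20, 0.06, 0.11, 0.11)
    _, arrays = run_cell(scen, 200, 9, return_arrays=True)
    sds = {m: arrays[m]["estimate"].std(ddof=1) for m in METHODS}
    for rep in range(200):
        ests = [arrays[m]["estimate"][rep] for m in METHODS]
        spread = max(ests) - min(ests)
        assert spread <= 3 * max(sds.values())


def make_result(est, lo, hi, p=0.5):
    return FitResult("m", est, 0.1, math.inf, est / 0.1, p, lo, hi)


def test_summarize_hand_computed_metrics():
    scen = SimScenario(6, 5, 0.03, 0.2, 0.11)
    fits = [
        {"m": make_result(0.1, 0.0, 0.2)},
        {"m": make_result(0.2, 0.1, 0.3)},
        {"m": make_result(0.3, 0.25, 0.35)},
    ]
    (row,) = summarize(fits, scen)
    assert row.rmse == pytest.approx(math.sqrt(0.02 / 3))
    assert row.rmse == pytest.approx(0.08165, abs=5e-6)
    assert row.coverage == pytest.approx(2 / 3)
    assert row.mean_ci_width == pytest.approx((0.2 + 0.2 + 0.1) / 3)
    assert row.n_converged == 3
    assert row.mc_se_rejection == pytest.approx(
        math.sqrt(row.rejection_rate * (1 - row.rejection_rate) / 3)
    )


def test_summarize_all_reject_and_zero_rmse():
    scen = SimScenario(6, 5, 0.03, 0.2, 0.11)
    fits = [{"m": make_result(0.2, 0.1, 0.3, p=0.001)} for _ in range(4)]
    (row,) = summarize(fits, scen)
    assert row.rejection_rate == 1.0
    assert row.rmse == 0.0


def test_non_converged_fits_are_excluded_and_counted():
    from stratcrt.results import failed_result

    scen = SimScenario(6, 5, 0.03, 0.0, 0.11)
    fits = [
        {"m": make_result(0.1, 0.0, 0.2)},
        {"m": failed_result("m")},
        {"m": make_result(0.3, 0.25, 0.35)},
    ]
    (row,) = summarize(fits, scen)
    assert row.n_reps == 3
    assert row.n_converged == 2
    assert not math.isnan(row.rmse)


def test_analyze_all_turns_failures_into_nonconverged():
    # J=2 per stratum: cluster-level regression (<5 clusters) and per-stratum
    # variances (1 treated cluster per stratum) are unavailable
    scen = SimScenario(2, 6, 0.06, 0.0, 0.11)
    data = __import__("stratcrt").generate_trial(scen, np.random.default_rng(5))
    res = analyze_all(data)
    assert res["lmm"].converged and res["gee"].converged
    assert not res["cl_regression"].converged
    assert not res["meta_regression"].converged


class TestEngineEquivalence:
    @pytest.mark.parametrize(
        "scen, seed",
        [
            (SimScenario(6, 5, 0.06, 0.11, 0.5), 7),
            (SimScenario(24, 10, 0.10, 0.0, 0.11), 3),
            (SimScenario(6, 50, 0.03, 0.5, 0.11), 11),
        ],
    )
    def test_balanced_engine_matches_general_fitters(self, scen, seed):
        """The vectorized closed forms reproduce the per-dataset fits
        replicate by replicate on identical substreams."""
        _, fast = run_cell(scen, 40, seed, engine="balanced", return_arrays=True)
        _, direct = run_cell(scen, 40, seed, engine="direct", return_arrays=True)
        for m in METHODS:
            for key in ("estimate", "se", "p_value", "ci_low", "ci_high"):
                np.testing.assert_allclose(
                    fast[m][key], direct[m][key], rtol=0, atol=5e-7,
                    err_msg=f"{m}/{key}",
                )

    def test_common_random_numbers_within_cell(self):
        """All methods analyze the same datasets: cluster-mean based point
        estimates are identical across lmm, gee and cl_regression."""
        scen = SimScenario(6, 10, 0.06, 0.0, 0.11)
        _, arrays = run_cell(scen, 100, 13, return_arrays=True)
        np.testing.assert_allclose(
            arrays["lmm"]["estimate"], arrays["cl_regression"]["estimate"], atol=1e-12
        )
        np.testing.assert_allclose(
            arrays["gee"]["estimate"], arrays["cl_regression"]["estimate"], atol=1e-12
        )


def test_run_grid_reproducible_and_complete(tmp_path):
    cfg = GridConfig(
        n_reps=10,
        seed=99,
        clusters_per_stratum=(6,),
        cluster_size=(5, 10),
        icc=(0.03,),
        beta1=(0.0,),
        beta2=(0.11,),
    )
    a = run_grid(cfg, out_dir=tmp_path)
    b = run_grid(cfg)
    assert len(a) == 2 * len(METHODS)
    pd.testing.assert_frame_equal(a, b)
    on_disk = pd.read_csv(tmp_path / "metrics.csv")
    assert len(on_disk) == len(a)


def test_cell_results_independent_of_grid_subset():
    """A cell's seed stream depends only on the master seed and its own
    parameters, so running it alone or inside a grid gives identical rows."""
    scen = SimScenario(6, 5, 0.03, 0.0, 0.11)
    alone = run_cell(scen, 25, 7)
    cfg = GridConfig(
        n_reps=25, seed=7, clusters_per_stratum=(6,), cluster_size=(5, 10),
        icc=(0.03, 0.06), beta1=(0.0,), beta2=(0.11,),
    )
    table = run_grid(cfg)
    sub = table[(table.cluster_size == 5) & np.isclose(table.icc, 0.03)]
    for row in alone:
        match = sub[sub.method == row.method].iloc[0]
        assert match.rejection_rate == row.rejection_rate
        assert match.rmse == row.rmse


def test_replicates_csv_allows_resummarizing(tmp_path):
    cfg = GridConfig(
        n_reps=30, seed=5, clusters_per_stratum=(6,), cluster_size=(5,),
        icc=(0.06,), beta1=(0.11,), beta2=(0.11,), keep_replicates=True,
    )
    table = run_grid(cfg, out_dir=tmp_path)
    reps = pd.read_csv(tmp_path / "replicates.csv")
    for m in METHODS:
        sub = reps[reps.method == m]
        rmse = np.sqrt(np.mean((sub.estimate - 0.11) ** 2))
        assert rmse == pytest.approx(
            float(table[table.method == m].rmse.iloc[0]), abs=1e-12
        )


class TestCrossSizeAverage:
    def make_table(self, values, sizes=None):
        sizes = sizes or [5, 10, 15, 20, 25, 30, 35, 40, 45, 50]
        return pd.DataFrame(
            {
                "method": "gee",
                "clusters_per_stratum": 24,
                "icc": 0.03,
                "beta1": 0.11,
                "beta2": 0.11,
                "cluster_size": sizes,
                "rejection_rate": values,
            }
        )

    def test_constant_metric(self):
        t = self.make_table([0.3] * 10)
        assert cross_size_average(
            t, "rejection_rate", {"method": "gee"}
        ) == pytest.approx(0.3)

    def test_arithmetic_mean(self):
        t = self.make_table(np.linspace(0.1, 1.0, 10))
        assert cross_size_average(
            t, "rejection_rate", {"method": "gee"}
        ) == pytest.approx(0.55)

    def test_incomplete_coverage_rejected(self):
        t = self.make_table(np.linspace(0.1, 0.9, 9), sizes=list(range(5, 50, 5)))
        with pytest.raises(ValueError, match="cover"):
            cross_size_average(t, "rejection_rate", {"method": "gee"})


class TestFigureTable:
    def test_pivot_layout_and_values(self):
        from stratcrt.figures import figure_table

        table = pd.DataFrame(
            {
                "method": ["gee", "gee", "lmm", "lmm"],
                "clusters_per_stratum": 24,
                "icc": 0.03,
                "beta1": [0.11, 0.11, 0.0, 0.0],
                "beta2": 0.11,
                "cluster_size": [5, 10, 5, 10],
                "rejection_rate": [0.2, 0.3, 0.05, 0.06],
            }
        )
        piv = figure_table(table, "rejection_rate", beta1=0.11)
        assert list(piv.columns) == [5, 10]
        assert piv.loc[(24, 0.03, "gee"), 5] == pytest.approx(0.2)
        assert (24, 0.03, "lmm") not in piv.index
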