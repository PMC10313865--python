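"""Monte Carlo study: run the method comparison over a scenario grid.

Every replicate of a grid cell is one simulated stratified CRT analyzed by
all four methods on the same data (common random numbers), and each cell is
summarized by the operating characteristics used to compare the methods:

1. rejection rate of H0: beta1 = 0 at the 5% level — the type I error rate
   when the generating beta1 is 0, the empirical power otherwise;
2. root mean square error sqrt(mean((estimate - beta1)^2));
3. mean width of the 95% confidence interval;
4. empirical coverage — the fraction of intervals containing beta1;

together with the Monte Carlo standard error of the rejection rate and the
count of converged fits (non-converged fits are excluded from a method's
metrics and reported).

Seeding: each cell derives its seed stream from the master seed and its own
parameter values, and spawns one substream per replicate.  Results are
therefore reproducible cell by cell, independent of which other cells run,
and identical whether a cell is executed through the vectorized
balanced-design engine (the default) or by looping the general per-dataset
fitters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._balanced import METHODS, BalancedCell
from .cluster_level import analyze_cl_regression, analyze_meta
from .gee import analyze_gee
from .lmm import analyze_lmm
from .results import FitResult, failed_result
from .simulate import DEFAULT_GRID, SimScenario, generate_trial

__all__ = [
    "METHODS",
    "MetricsRow",
    "GridConfig",
    "run_replicate",
    "summarize",
    "run_grid",
    "cross_size_average",
    "analyze_all",
]

ALPHA = 0.05

_ANALYZERS = {
    "lmm": analyze_lmm,
    "gee": analyze_gee,
    "cl_regression": analyze_cl_regression,
    "meta_regression": analyze_meta,
}

SCENARIO_FIELDS = ("clusters_per_stratum", "cluster_size", "icc", "beta1", "beta2")


@dataclass(frozen=True)
class MetricsRow:
    """Operating characteristics of one method in one scenario cell."""

    scenario: SimScenario
    method: str
    n_reps: int
    n_converged: int
    rejection_rate: float
    rmse: float
    mean_ci_width: float
    coverage: float
    mc_se_rejection: float
    mean_estimate: float
    mean_se: float

    def to_dict(self) -> dict:
        d = {f: getattr(self.scenario, f) for f in SCENARIO_FIELDS}
        d.update(
            method=self.method,
            n_reps=self.n_reps,
            n_converged=self.n_converged,
            rejection_rate=self.rejection_rate,
            rmse=self.rmse,
            mean_ci_width=self.mean_ci_width,
            coverage=self.coverage,
            mc_se_rejection=self.mc_se_rejection,
            mean_estimate=self.mean_estimate,
            mean_se=self.mean_se,
        )
        return d


def analyze_all(
    data: pd.DataFrame, methods: Sequence[str] = METHODS
) -> dict[str, FitResult]:
    """All requested methods on one trial; failures become non-converged results."""
    out = {}
    for m in methods:
        try:
            out[m] = _ANALYZERS[m](data)
        except Exception:
            out[m] = failed_result(m)
    return out


def run_replicate(
    scenario: SimScenario,
    rng: np.random.Generator,
    methods: Sequence[str] = METHODS,
) -> dict[str, FitResult]:
    """Generate one trial and analyze it with every method."""
    return analyze_all(generate_trial(scenario, rng), methods)


def _metrics_from_arrays(
    scenario: SimScenario, method: str, arrays: Mapping[str, np.ndarray]
) -> MetricsRow:
    ok = np.asarray(arrays["converged"], dtype=bool)
    n_reps = len(ok)
    n_conv = int(ok.sum())
    if n_conv < 2:
        nan = float("nan")
        return MetricsRow(
            scenario, method, n_reps, n_conv, nan, nan, nan, nan, nan, nan, nan
        )
    est = np.asarray(arrays["estimate"])[ok]
    p = np.asarray(arrays["p_value"])[ok]
    lo = np.asarray(arrays["ci_low"])[ok]
    hi = np.asarray(arrays["ci_high"])[ok]
    se = np.asarray(arrays["se"])[ok]
    b1 = scenario.beta1
    reject = float(np.mean(p < ALPHA))
    return MetricsRow(
        scenario=scenario,
        method=method,
        n_reps=n_reps,
        n_converged=n_conv,
        rejection_rate=reject,
        rmse=float(np.sqrt(np.mean((est - b1) ** 2))),
        mean_ci_width=float(np.mean(hi - lo)),
        coverage=float(np.mean((lo <= b1) & (b1 <= hi))),
        mc_se_rejection=float(np.sqrt(reject * (1.0 - reject) / n_conv)),
        mean_estimate=float(np.mean(est)),
        mean_se=float(np.mean(se)),
    )


def summarize(
    results: Sequence[Mapping[str, FitResult]], scenario: SimScenario
) -> list[MetricsRow]:
    """Operating characteristics per method from per-replicate fit results."""
    if len(results) < 2:
        raise ValueError("need at least two replicates to summarize")
    rows = []
    for m in results[0]:
        fits = [r[m] for r in results]
        arrays = {
            "converged": np.array([f.converged for f in fits]),
            "estimate": np.array([f.estimate for f in fits]),
            "p_value": np.array([f.p_value for f in fits]),
            "ci_low": np.array([f.ci_low for f in fits]),
            "ci_high": np.array([f.ci_high for f in fits]),
            "se": np.array([f.se for f in fits]),
        }
        rows.append(_metrics_from_arrays(scenario, m, arrays))
    return rows


@dataclass
class GridConfig:
    """Configuration of a simulation run over (a subset of) the study grid."""

    n_reps: int = 2500
    seed: int = 20230314
    clusters_per_stratum: tuple = DEFAULT_GRID["clusters_per_stratum"]
    cluster_size: tuple = DEFAULT_GRID["cluster_size"]
    icc: tuple = DEFAULT_GRID["icc"]
    beta1: tuple = DEFAULT_GRID["beta1"]
    beta2: tuple = DEFAULT_GRID["beta2"]
    methods: tuple = METHODS
    engine: str = "balanced"  # "balanced" (vectorized) or "direct"
    keep_replicates: bool = False

    def scenarios(self) -> list[SimScenario]:
        return [
            SimScenario(j, n, rho, b1, b2)
            for j in self.clusters_per_stratum
            for n in self.cluster_size
            for rho in self.icc
            for b1 in self.beta1
            for b2 in self.beta2
        ]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GridConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in (
            "n_reps",
            "seed",
            "clusters_per_stratum",
            "cluster_size",
            "icc",
            "beta1",
            "beta2",
            "methods",
            "engine",
            "keep_replicates",
        ):
            if key in raw:
                val = raw[key]
                kwargs[key] = tuple(val) if isinstance(val, (list, tuple)) else val
        return cls(**kwargs)


def cell_seed_sequence(master_seed: int, scenario: SimScenario) -> np.random.SeedSequence:
    """Seed stream for one grid cell, a pure function of seed and parameters.

    Encoding the cell parameters into the entropy makes a cell's replicates
    identical whether it is run alone or as part of any grid subset.
    """
    entropy = (
        int(master_seed),
        scenario.clusters_per_stratum,
        scenario.cluster_size,
        round(scenario.icc * 10_000),
        round(scenario.beta1 * 10_000),
        round(scenario.beta2 * 10_000),
    )
    return np.random.SeedSequence(entropy)


def run_cell(
    scenario: SimScenario,
    n_reps: int,
    master_seed: int,
    methods: Sequence[str] = METHODS,
    engine: str = "balanced",
    return_arrays: bool = False,
):
    """Run one grid cell; returns MetricsRows (and per-replicate arrays if asked)."""
    substreams = cell_seed_sequence(master_seed, scenario).spawn(n_reps)
    if engine == "balanced":
        cell = BalancedCell(scenario)
        means, ssw = cell.simulate_batch(substreams)
        per_method = cell.analyze_batch(means, ssw)
        per_method = {m: per_method[m] for m in methods}
    elif engine == "direct":
        results = [
            run_replicate(scenario, np.random.default_rng(ss), methods)
            for ss in substreams
        ]
        per_method = {
            m: {
                "converged": np.array([r[m].converged for r in results]),
                "estimate": np.array([r[m].estimate for r in results]),
                "p_value": np.array([r[m].p_value for r in results]),
                "ci_low": np.array([r[m].ci_low for r in results]),
                "ci_high": np.array([r[m].ci_high for r in results]),
                "se": np.array([r[m].se for r in results]),
            }
            for m in methods
        }
    else:
        raise ValueError(f"unknown engine {engine!r}")
    rows = [_metrics_from_arrays(scenario, m, arr) for m, arr in per_method.items()]
    if return_arrays:
        return rows, per_method
    return rows


def run_grid(
    config: GridConfig,
    out_dir: str | Path | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every cell of the configured grid; long-format metrics table.

    If ``out_dir`` is given, writes ``metrics.csv`` (one row per cell and
    method) and, when ``keep_replicates`` is set, ``replicates.csv`` with the
    per-replicate estimates so metrics can be recomputed without refitting.
    """
    rows = []
    rep_frames = []
    scenarios = config.scenarios()
    for i, scen in enumerate(scenarios):
        if config.keep_replicates:
            cell_rows, arrays = run_cell(
                scen, config.n_reps, config.seed, config.methods,
                config.engine, return_arrays=True,
            )
            for m, arr in arrays.items():
                df = pd.DataFrame(
                    {
                        "replicate": np.arange(config.n_reps),
                        "method": m,
                        "estimate": arr["estimate"],
                        "se": arr["se"],
                        "p_value": arr["p_value"],
                        "ci_low": arr["ci_low"],
                        "ci_high": arr["ci_high"],
                        "converged": arr["converged"],
                    }
                )
                for f in SCENARIO_FIELDS:
                    df[f] = getattr(scen, f)
                rep_frames.append(df)
        else:
            cell_rows = run_cell(
                scen, config.n_reps, config.seed, config.methods, config.engine
            )
        rows.extend(cell_rows)
        if progress:
            print(f"[{i + 1}/{len(scenarios)}] {scen}", flush=True)
    table = pd.DataFrame([r.to_dict() for r in rows])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "metrics.csv", index=False)
        if rep_frames:
            pd.concat(rep_frames, ignore_index=True).to_csv(
                out / "replicates.csv", index=False
            )
        failures = table[table["n_converged"] < table["n_reps"]]
        if len(failures):
            failures.to_csv(out / "convergence_failures.csv", index=False)
    return table


def cross_size_average(
    table: pd.DataFrame,
    metric: str,
    where: Mapping[str, object],
    sizes: Iterable[int] = DEFAULT_GRID["cluster_size"],
) -> float:
    """Mean of a metric across the cluster-size axis of the grid.

    ``where`` filters the long-format table (e.g. ``{"method": "gee",
    "clusters_per_stratum": 24, "icc": 0.03, "beta1": 0.11}``); the filtered
    rows must cover every cluster size in ``sizes`` the same number of times,
    otherwise the average would silently mix incomplete margins.
    """
    sizes = sorted(sizes)
    mask = np.ones(len(table), dtype=bool)
    for key, val in where.items():
        col = table[key]
        if isinstance(val, (list, tuple, set, frozenset)):
            mask &= col.isin(list(val)).to_numpy()
        elif isinstance(val, float):
            mask &= np.isclose(col.to_numpy(dtype=float), val)
        else:
            mask &= (col == val).to_numpy()
    sub = table[mask]
    counts = sub["cluster_size"].value_counts()
    if sorted(counts.index) != sizes or counts.nunique() != 1:
        raise ValueError(
            f"filtered table does not cover cluster sizes {sizes} evenly: "
            f"{counts.to_dict()}"
        )
    return float(sub[metric].mean())
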