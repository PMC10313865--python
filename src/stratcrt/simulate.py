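"""Synthetic stratified cluster-randomized-trial (CRT) data.

Datasets are generated from a random-intercept linear model for a two-arm,
two-stratum design in which intact clusters are randomized 1:1 to arms
within each stratum:

    Y_ijks = beta0 + beta1 * X_ijks + beta2 * S_ijks + C_jk + e_ijks

where X is the arm indicator, S the stratum indicator, C_jk ~ N(0, sigma_b^2)
a cluster-level random effect and e_ijks ~ N(0, sigma_e^2) an individual
error.  The intra-cluster correlation coefficient (ICC) is
sigma_b^2 / (sigma_b^2 + sigma_e^2); the total variance is fixed by the
scenario (default 1) so the ICC alone determines the variance split.

A trial dataset is a :class:`pandas.DataFrame` with one row per individual
and columns ``cluster_id`` (globally unique integer), ``stratum`` (0/1),
``arm`` (0/1) and ``y`` (float).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

TRIAL_COLUMNS = ("cluster_id", "stratum", "arm", "y")

#: Parameter grid of the simulation study: every combination of these values
#: defines one scenario cell.
DEFAULT_GRID = {
    "clusters_per_stratum": (6, 24, 34, 68),
    "cluster_size": (5, 10, 15, 20, 25, 30, 35, 40, 45, 50),
    "icc": (0.03, 0.06, 0.10),
    "beta1": (0.0, 0.11, 0.50),
    "beta2": (0.11, 0.50),
}


class InvalidParameterError(ValueError):
    """A scenario or variance parameter is outside its valid range."""


@dataclass(frozen=True)
class VarianceComponents:
    """Between-cluster and within-cluster variances of the outcome."""

    sigma_b2: float
    sigma_e2: float

    @property
    def total(self) -> float:
        return self.sigma_b2 + self.sigma_e2

    @property
    def icc(self) -> float:
        return self.sigma_b2 / self.total


def variance_components_from_icc(
    icc: float, total_variance: float = 1.0
) -> VarianceComponents:
    """Split a total variance into cluster and residual components.

    The ICC is the ratio of the between-cluster variance to the total
    variance, so ``sigma_b2 = icc * total`` and ``sigma_e2 = (1 - icc) * total``.

    Parameters
    ----------
    icc
        Intra-cluster correlation coefficient, in ``[0, 1)``.
    total_variance
        Total outcome variance ``sigma_b2 + sigma_e2``; must be positive.
    """
    if not 0.0 <= icc < 1.0:
        raise InvalidParameterError(f"icc must be in [0, 1), got {icc!r}")
    if not total_variance > 0:
        raise InvalidParameterError(
            f"total_variance must be positive, got {total_variance!r}"
        )
    return VarianceComponents(icc * total_variance, (1.0 - icc) * total_variance)


@dataclass(frozen=True)
class SimScenario:
    """One cell of the simulation grid.

    Parameters
    ----------
    clusters_per_stratum
        Total clusters in each stratum (J); must be even so the 1:1
        within-stratum allocation is exact.
    cluster_size
        Individuals per cluster, equal for all clusters.
    icc
        Intra-cluster correlation coefficient.
    beta1
        Treatment effect on the outcome scale.
    beta2
        Stratum effect on the outcome scale.
    beta0
        Control-arm, stratum-0 mean (0 by convention).
    total_variance
        sigma_b^2 + sigma_e^2 (1 by convention).
    """

    clusters_per_stratum: int
    cluster_size: int
    icc: float
    beta1: float
    beta2: float
    beta0: float = 0.0
    total_variance: float = 1.0
    n_strata: int = field(default=2, repr=False)

    def __post_init__(self) -> None:
        if self.clusters_per_stratum <= 0 or self.clusters_per_stratum % 2 != 0:
            raise InvalidParameterError(
                "clusters_per_stratum must be a positive even integer, got "
                f"{self.clusters_per_stratum!r}"
            )
        if self.cluster_size <= 0:
            raise InvalidParameterError(
                f"cluster_size must be positive, got {self.cluster_size!r}"
            )
        if self.n_strata != 2:
            raise InvalidParameterError("only two strata are supported")
        # validates icc / total_variance ranges
        variance_components_from_icc(self.icc, self.total_variance)

    @property
    def n_clusters(self) -> int:
        """Total clusters across both strata."""
        return self.n_strata * self.clusters_per_stratum

    @property
    def n_individuals(self) -> int:
        return self.n_clusters * self.cluster_size

    @property
    def variance_components(self) -> VarianceComponents:
        return variance_components_from_icc(self.icc, self.total_variance)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("n_strata")
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimScenario":
        return cls(
            clusters_per_stratum=int(d["clusters_per_stratum"]),
            cluster_size=int(d["cluster_size"]),
            icc=float(d["icc"]),
            beta1=float(d["beta1"]),
            beta2=float(d["beta2"]),
            beta0=float(d.get("beta0", 0.0)),
            total_variance=float(d.get("total_variance", 1.0)),
        )


def cluster_design(
    scenario: SimScenario, permute_arms: bool = False, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Cluster-level design table: one row per cluster.

    Cluster ids are globally unique integers (0 .. 2J-1); stratum 0 holds the
    first J.  By default the first J/2 clusters of each stratum are assigned
    to the treatment arm — a deterministic labelling that is distributionally
    equivalent to randomized assignment because the cluster effects are
    exchangeable.  ``permute_arms=True`` randomizes the labels instead.
    """
    j = scenario.clusters_per_stratum
    strata = np.repeat([0, 1], j)
    arms = np.tile(np.r_[np.ones(j // 2, dtype=int), np.zeros(j - j // 2, dtype=int)], 2)
    if permute_arms:
        if rng is None:
            raise ValueError("permute_arms=True requires an rng")
        for s in (0, 1):
            idx = np.where(strata == s)[0]
            arms[idx] = arms[rng.permutation(idx)]
    return pd.DataFrame(
        {
            "cluster_id": np.arange(scenario.n_clusters),
            "stratum": strata,
            "arm": arms,
        }
    )


def _draw_effects(
    scenario: SimScenario, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the latent cluster effects (K,) and errors (K, n).

    The draw order (all cluster effects, then all errors, cluster-major) is
    part of the reproducibility contract: any consumer using the same
    substream obtains the same trial.
    """
    vc = scenario.variance_components
    k, n = scenario.n_clusters, scenario.cluster_size
    cluster_effects = rng.standard_normal(k) * np.sqrt(vc.sigma_b2)
    errors = rng.standard_normal((k, n)) * np.sqrt(vc.sigma_e2)
    return cluster_effects, errors


def generate_trial(
    scenario: SimScenario,
    rng: np.random.Generator,
    permute_arms: bool = False,
) -> pd.DataFrame:
    """Simulate one stratified CRT as an individual-level DataFrame.

    Outcomes follow the random-intercept model
    ``y = beta0 + beta1*arm + beta2*stratum + C_cluster + e`` with
    ``C ~ N(0, icc * total_variance)`` and ``e ~ N(0, (1-icc) * total_variance)``.

    Returns a DataFrame with columns ``cluster_id, stratum, arm, y``; each
    cluster contributes exactly ``cluster_size`` consecutive rows.
    """
    design = cluster_design(scenario, permute_arms=permute_arms, rng=rng)
    cluster_effects, errors = _draw_effects(scenario, rng)
    n = scenario.cluster_size
    mean = (
        scenario.beta0
        + scenario.beta1 * design["arm"].to_numpy()
        + scenario.beta2 * design["stratum"].to_numpy()
    )
    y = mean[:, None] + cluster_effects[:, None] + errors
    return pd.DataFrame(
        {
            "cluster_id": np.repeat(design["cluster_id"].to_numpy(), n),
            "stratum": np.repeat(design["stratum"].to_numpy(), n),
            "arm": np.repeat(design["arm"].to_numpy(), n),
            "y": y.ravel(),
        }
    )


def validate_trial(data: pd.DataFrame) -> pd.DataFrame:
    """Check the trial-data schema and cluster-level consistency.

    Every cluster must carry a single stratum and a single arm label, and
    both arms must be present.  Returns the validated frame (unchanged).
    """
    missing = [c for c in TRIAL_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"trial data is missing columns {missing}")
    if data.empty:
        raise ValueError("trial data is empty")
    for col in ("stratum", "arm"):
        vals = set(pd.unique(data[col]))
        if not vals <= {0, 1}:
            raise ValueError(f"{col} must be coded 0/1, found {sorted(vals)}")
    per_cluster = data.groupby("cluster_id")[["stratum", "arm"]].nunique()
    bad = per_cluster[(per_cluster > 1).any(axis=1)]
    if len(bad):
        raise ValueError(
            f"clusters with inconsistent stratum/arm labels: {list(bad.index)}"
        )
    return data


def write_trial_csv(data: pd.DataFrame, path: str | Path) -> None:
    """Write individual-level trial data as CSV (header ``cluster_id,stratum,arm,y``)."""
    validate_trial(data)
    data.loc[:, list(TRIAL_COLUMNS)].to_csv(path, index=False)


def read_trial_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate an individual-level trial CSV."""
    data = pd.read_csv(path)
    return validate_trial(data)


def scenario_to_yaml(scenario: SimScenario, path: str | Path) -> None:
    """Persist a scenario as a flat key-value YAML document."""
    Path(path).write_text(yaml.safe_dump(scenario.to_dict(), sort_keys=False))


def scenario_from_yaml(path: str | Path) -> SimScenario:
    """Load a scenario from a flat key-value YAML document."""
    return SimScenario.from_dict(yaml.safe_load(Path(path).read_text()))


def default_grid(
    beta1: Iterable[float] | None = None,
    beta2: Iterable[float] | None = None,
    clusters_per_stratum: Iterable[int] | None = None,
    cluster_size: Iterable[int] | None = None,
    icc: Iterable[float] | None = None,
) -> list[SimScenario]:
    """Enumerate scenario cells of the study grid.

    Any axis left as ``None`` takes the full default set; ordering is
    deterministic (J, size, ICC, beta1, beta2 — slowest to fastest).
    """

    def pick(name: str, given: Iterable | None) -> Sequence:
        return tuple(given) if given is not None else DEFAULT_GRID[name]

    cells = []
    for j in pick("clusters_per_stratum", clusters_per_stratum):
        for n in pick("cluster_size", cluster_size):
            for rho in pick("icc", icc):
                for b1 in pick("beta1", beta1):
                    for b2 in pick("beta2", beta2):
                        cells.append(
                            SimScenario(
                                clusters_per_stratum=j,
                                cluster_size=n,
                                icc=rho,
                                beta1=b1,
                                beta2=b2,
                            )
                        )
    return cells
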