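"""Summary tables and plots of the metrics grid.

The study's results are read as one panel per number of clusters, one line
per ICC, cluster size on the x axis.  ``figure_table`` pivots the long-format
metrics into exactly that layout; ``plot_metric`` draws it with matplotlib
(an optional dependency of this module only).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def figure_table(
    table: pd.DataFrame, metric: str, beta1: float | None = None
) -> pd.DataFrame:
    """Pivot a metrics table to (J, ICC, method) rows x cluster-size columns."""
    sub = table
    if beta1 is not None:
        sub = sub[np.isclose(sub["beta1"], beta1)]
    return sub.pivot_table(
        index=["clusters_per_stratum", "icc", "method"],
        columns="cluster_size",
        values=metric,
    )


def plot_metric(
    table: pd.DataFrame,
    metric: str,
    beta1: float | None = None,
    out_path: str | None = None,
):
    """One panel per clusters-per-stratum; method x ICC lines over cluster size."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = table
    if beta1 is not None:
        sub = sub[np.isclose(sub["beta1"], beta1)]
    js = sorted(sub["clusters_per_stratum"].unique())
    iccs = sorted(sub["icc"].unique())
    fig, axes = plt.subplots(
        len(iccs), len(js), figsize=(4 * len(js), 3 * len(iccs)),
        sharex=True, sharey=True, squeeze=False,
    )
    for r, icc in enumerate(iccs):
        for c, j in enumerate(js):
            ax = axes[r][c]
            cell = sub[
                (sub["clusters_per_stratum"] == j) & np.isclose(sub["icc"], icc)
            ]
            for method, grp in cell.groupby("method"):
                grp = grp.sort_values("cluster_size")
                ax.plot(grp["cluster_size"], grp[metric], marker="o", label=method)
            ax.set_title(f"J={j}/stratum, ICC={icc}")
            if r == len(iccs) - 1:
                ax.set_xlabel("cluster size")
            if c == 0:
                ax.set_ylabel(metric)
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return fig
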