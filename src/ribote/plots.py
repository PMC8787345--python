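"""Figure-level plots for the association analyses.

All functions take an optional ``path``; when given, the figure is saved
and closed, otherwise the matplotlib Figure is returned.
"""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .assoc import CorrelationResult


def _finish(fig, path):
    if path is None:
        return fig
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
    return None


def correlation_scatter(x, y, result: CorrelationResult,
                        xlabel: str = "", ylabel: str = "", path=None):
    """Scatter of two vectors annotated with rho and p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x[ok], y[ok], s=6, alpha=0.4, edgecolors="none")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(f"{result.method} rho = {result.rho:.2f}, "
                 f"p = {result.p:.2g} (n = {result.n})", fontsize=9)
    return _finish(fig, path)


def group_boxplot(values, labels, ylabel: str = "", path=None):
    """Box-and-whisker panel of a feature split by category."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    names = sorted(pd.unique(labels))
    data = [values[labels == name] for name in names]
    fig, ax = plt.subplots(figsize=(1.2 * max(len(names), 3), 4))
    ax.boxplot(data, tick_labels=[str(n) for n in names], showfliers=False)
    ax.set_ylabel(ylabel)
    return _finish(fig, path)


def clustered_heatmap(matrix: pd.DataFrame, clustering: dict, path=None):
    """Heatmap of delta-TE profiles ordered by a cluster_delta_te result,
    with the dendrogram alongside."""
    order = clustering["leaf_order"]
    mat = matrix.loc[order]
    fig, (ax_d, ax_h) = plt.subplots(
        1, 2, figsize=(6, max(3, 0.05 * len(mat))),
        gridspec_kw={"width_ratios": [1, 3]})
    hierarchy.dendrogram(clustering["linkage"], ax=ax_d, orientation="left",
                         no_labels=True, color_threshold=0)
    ax_d.set_xticks([])
    vmax = np.nanmax(np.abs(mat.to_numpy())) or 1.0
    im = ax_h.imshow(mat.to_numpy(), aspect="auto", cmap="RdBu_r",
                     vmin=-vmax, vmax=vmax, interpolation="nearest")
    ax_h.set_yticks([])
    ax_h.set_xticks(range(mat.shape[1]))
    ax_h.set_xticklabels(mat.columns, rotation=45, ha="right", fontsize=7)
    fig.colorbar(im, ax=ax_h, shrink=0.6, label="log2 delta-TE")
    return _finish(fig, path)
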