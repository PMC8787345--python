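"""Association statistics: correlations, set overlaps, group contrasts,
and clustering of delta-TE profiles."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy



@dataclass(frozen=True)
class CorrelationResult:
    method: str
    rho: float
    p: float
    n: int
    reason: str | None = None  # set when the statistic is undefined

    @property
    def defined(self) -> bool:
        return self.reason is None


@dataclass(frozen=True)
class OverlapResult:
    n_universe: int
    n_a: int
    n_b: int
    n_overlap: int
    p_hyper: float


@dataclass(frozen=True)
class GroupTestResult:
    test: str
    groups: tuple[str, ...]
    statistic: float
    p: float | None = None
    pairwise_padj: pd.DataFrame | None = None


def correlate(x, y, method: str = "spearman") -> CorrelationResult:
    """Correlation with pairwise deletion of missing values.

    Spearman is Pearson on average ranks with a t-approximation p
    (n - 2 df); Pearson p likewise. Zero variance in either vector makes
    the statistic undefined (returned with a reason, not an error).
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(method, np.nan, np.nan, n,
                                 reason="zero variance")
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return CorrelationResult(method, np.nan, np.nan, n,
                                     reason="zero variance in ranks")
    rho = float(np.corrcoef(x, y)[0, 1])
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(method, rho, p, n)


def overlap_test(a: set, b: set, universe: set) -> OverlapResult:
    """Exact hypergeometric enrichment test of the overlap of two gene sets.

    p = P(X >= |a & b|) with X ~ Hypergeom(N=|universe|, K=|a|, n=|b|).
    """
    a, b, universe = set(a), set(b), set(universe)
    stray = (a | b) - universe
    if stray:
        raise ValueError(
            f"sets not contained in universe: {sorted(stray)[:10]}"
        )
    n_universe, n_a, n_b = len(universe), len(a), len(b)
    n_overlap = len(a & b)
    p = float(stats.hypergeom.sf(n_overlap - 1, n_universe, n_a, n_b))
    return OverlapResult(n_universe, n_a, n_b, n_overlap, min(p, 1.0))


def compare_two_groups(values, labels) -> GroupTestResult:
    """Two-sided Wilcoxon rank-sum test between two groups.

    Exact null when the smaller group has <= 8 observations and there are
    no ties; otherwise normal approximation with continuity correction.
    Missing values are dropped.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    names = sorted(pd.unique(labels))
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 groups, got {names}")
    g1 = values[labels == names[0]]
    g2 = values[labels == names[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([g1, g2])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = min(len(g1), len(g2)) <= 8 and not has_ties
    res = stats.mannwhitneyu(
        g1, g2, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    p = float(res.pvalue)
    # perfectly balanced rank sums: two-sided p is 1 by symmetry, which the
    # continuity-corrected normal approximation misses slightly
    if res.statistic == len(g1) * len(g2) / 2:
        p = 1.0
    return GroupTestResult(
        test="wilcoxon", groups=tuple(str(x) for x in names),
        statistic=float(res.statistic), p=p,
    )


def compare_multi_groups(values, labels) -> GroupTestResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons (>= 3 groups).

    Returns the F statistic and p plus a symmetric DataFrame of pairwise
    Tukey-adjusted p-values. All-identical data leaves F undefined (NaN).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    names = sorted(pd.unique(labels))
    if len(names) < 3:
        raise ValueError("need at least 3 groups")
    groups = [values[labels == name] for name in names]
    for name, g in zip(names, groups):
        if len(g) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    if np.ptp(values) == 0:
        table = pd.DataFrame(np.nan, index=[str(n) for n in names],
                             columns=[str(n) for n in names])
        return GroupTestResult("anova_tukey", tuple(str(n) for n in names),
                               np.nan, p=np.nan, pairwise_padj=table)
    f_stat, f_p = stats.f_oneway(*groups)
    tukey = stats.tukey_hsd(*groups)
    k = len(names)
    table = pd.DataFrame(np.nan, index=[str(n) for n in names],
                         columns=[str(n) for n in names])
    for i in range(k):
        for j in range(k):
            if i != j:
                table.iloc[i, j] = tukey.pvalue[i, j]
    return GroupTestResult("anova_tukey", tuple(str(n) for n in names),
                           float(f_stat), p=float(f_p), pairwise_padj=table)


def cluster_delta_te(matrix: pd.DataFrame,
                     impute_missing: bool = True) -> dict:
    """Hierarchical clustering of genes over delta-TE datasets.

    Euclidean distance, Ward linkage. Missing entries are imputed as 0
    (no change) and flagged, unless ``impute_missing`` is False in which
    case incomplete rows are dropped. Deterministic for a given row order.
    """
    if impute_missing:
        flagged = matrix.index[matrix.isna().any(axis=1)]
        filled = matrix.fillna(0.0)
    else:
        flagged = pd.Index([])
        filled = matrix.dropna()
    if len(filled) < 2:
        raise ValueError("need at least 2 complete rows to cluster")
    linkage = hierarchy.linkage(filled.to_numpy(dtype=float),
                                method="ward", metric="euclidean")
    leaves = hierarchy.leaves_list(linkage)
    return {
        "linkage": linkage,
        "leaf_order": list(filled.index[leaves]),
        "merge_heights": linkage[:, 2].tolist(),
        "imputed_genes": list(flagged),
        "gene_ids": list(filled.index),
    }


def compare_external(te: pd.DataFrame, external: pd.DataFrame,
                     alpha: float = 0.05) -> dict:
    """Compare a delta-TE result table to an external delta-TE dataset.

    Pearson correlation of log2 delta-TE over the shared (intersection)
    gene universe, plus hypergeometric overlaps of the up-regulated and
    down-regulated significant sets. ``external`` needs ``log2_dte`` and,
    for the overlaps, ``padj``.
    """
    shared = te.index.intersection(external.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between datasets")
    corr = correlate(te.loc[shared, "log2_dte"],
                     external.loc[shared, "log2_dte"], method="pearson")
    out = {"correlation": corr, "n_shared": len(shared)}
    if "padj" in external.columns and "padj" in te.columns:
        universe = set(shared)
        for direction, cmp in (("up", 1), ("down", -1)):
            a = {g for g in shared
                 if te.loc[g, "padj"] < alpha and cmp * te.loc[g, "log2_dte"] > 0}
            b = {g for g in shared
                 if external.loc[g, "padj"] < alpha
                 and cmp * external.loc[g, "log2_dte"] > 0}
            out[f"overlap_{direction}"] = overlap_test(a, b, universe)
    return out


def group_contrast_with_adjustment(values, labels) -> GroupTestResult:
    """Dispatch to the two-group or multi-group contrast by label count."""
    n_groups = len(pd.unique(np.asarray(labels)[np.isfinite(np.asarray(values, dtype=float))]))
    if n_groups == 2:
        return compare_two_groups(values, labels)
    return compare_multi_groups(values, labels)
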