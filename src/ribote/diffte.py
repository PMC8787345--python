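"""Relative translational efficiency (TE_rel) and differential-TE testing.

The model is a per-gene negative-binomial log-linear model over the
2 (assay: RP, RNA) x 2 (condition: WT, MUT) design with library size
factors as offsets. NB parameterization throughout:
``variance = mean + dispersion * mean**2``.

Because the interaction design is saturated over the four design cells,
the interaction MLE has a closed form: each cell's fitted mean is the
arithmetic mean of the size-factor-normalized counts in that cell, and

    log2_dte = log2[(RP_mut / RNA_mut) / (RP_wt / RNA_wt)]

with a delta-method Wald standard error that carries the per-assay NB
dispersion and the per-sample size factors. This closed form is exactly
invariant under rescaling any library together with its size factor.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .models import CountMatrix

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8

CATEGORIES = ("up100", "up50", "down100", "down50", "sig_small", "ns")


# ---------------------------------------------------------------------------
# Normalization


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    For each sample, the factor is the median over genes (restricted to
    rows positive in every sample) of count / per-gene geometric mean.
    If no row is positive everywhere, falls back to total-count ratios
    (scaled to geometric mean 1) with a warning.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if positive.any():
        logmat = np.log(mat[positive])
        log_gmean = logmat.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logmat - log_gmean, axis=0))
    else:
        logger.warning("size_factors: no gene positive in all samples; "
                       "falling back to total-count ratios")
        totals = mat.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("size_factors: a sample has zero total counts")
        factors = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    return counts / factors.loc[counts.columns]


# ---------------------------------------------------------------------------
# TE_rel


def compute_te_rel(rp_norm: pd.DataFrame, rna_norm: pd.DataFrame,
                   samples: pd.DataFrame) -> pd.DataFrame:
    """Per-gene TE_rel by condition: normalized RP / normalized RNA,
    ratios taken per replicate pair and averaged within condition.

    Replicates are paired by their ``replicate`` index. Ratios with zero
    RNA are missing; a condition with no valid ratio yields NaN.
    """
    genes = rp_norm.index.intersection(rna_norm.index)
    out = {}
    for cond in ("WT", "MUT"):
        ratios = []
        meta = samples[samples["condition"] == cond]
        for rep in sorted(meta["replicate"].unique()):
            rp_col = meta[(meta["assay"] == "RP") & (meta["replicate"] == rep)].index
            rna_col = meta[(meta["assay"] == "RNA") & (meta["replicate"] == rep)].index
            if len(rp_col) != 1 or len(rna_col) != 1:
                continue
            rp = rp_norm.loc[genes, rp_col[0]]
            rna = rna_norm.loc[genes, rna_col[0]].replace(0.0, np.nan)
            ratios.append(rp / rna)
        if not ratios:
            raise ValueError(f"no complete replicate pairs for condition {cond}")
        out[f"te_{cond.lower()}"] = pd.concat(ratios, axis=1).mean(axis=1)
    df = pd.DataFrame(out, index=genes)
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        logger.info("compute_te_rel: %d gene(s) with missing TE (zero RNA)", n_missing)
    return df


# ---------------------------------------------------------------------------
# Dispersion


def estimate_dispersion(cm: CountMatrix, factors: pd.Series,
                        shrinkage_weight: float = 0.7) -> pd.DataFrame:
    """Per-gene NB dispersion for one assay's count matrix.

    Method-of-moments on normalized counts within each condition,
    ``max((var - mean) / mean**2, 1e-8)`` averaged over conditions, then
    shrunk toward a ``a1 + a0/mean`` trend fitted across genes:
    ``shrunk = (1 - w) * genewise + w * trend``.

    Genes with no usable moment estimate (constant or zero counts) get
    the trend value and are flagged in the ``from_trend`` column.
    """
    if not 0.0 <= shrinkage_weight <= 1.0:
        raise ValueError("shrinkage_weight must be in [0, 1]")
    meta = cm.samples.loc[list(cm.counts.columns)]
    norm = normalize(cm.counts, factors)
    per_cond = []
    for cond in meta["condition"].unique():
        cols = meta.index[meta["condition"] == cond]
        if len(cols) < 2:
            raise ValueError(f"condition {cond}: need >= 2 replicates")
        sub = norm[cols].to_numpy(dtype=float)
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where((m > 0) & (v > 0), (v - m) / m**2, np.nan)
        per_cond.append(d)
    stacked = np.column_stack(per_cond)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        genewise = np.nanmean(stacked, axis=1)  # all-NaN rows stay NaN
    genewise = np.where(np.isnan(genewise), np.nan,
                        np.maximum(genewise, DISPERSION_FLOOR))
    base_mean = norm.to_numpy(dtype=float).mean(axis=1)

    trend = _fit_dispersion_trend(base_mean, genewise)
    from_trend = np.isnan(genewise)
    shrunk = np.where(
        from_trend, trend,
        (1.0 - shrinkage_weight) * genewise + shrinkage_weight * trend,
    )
    shrunk = np.maximum(shrunk, DISPERSION_FLOOR)
    return pd.DataFrame(
        {"base_mean": base_mean, "genewise": genewise, "trend": trend,
         "dispersion": shrunk, "from_trend": from_trend},
        index=cm.counts.index,
    )


def _fit_dispersion_trend(mean: np.ndarray, genewise: np.ndarray) -> np.ndarray:
    """Least-squares fit of dispersion ~ a1 + a0 / mean, coefficients >= 0."""
    ok = np.isfinite(genewise) & (mean > 0)
    fallback = float(np.nanmedian(genewise[ok])) if ok.any() else 0.1
    if ok.sum() < 10:
        return np.full_like(mean, max(fallback, DISPERSION_FLOOR), dtype=float)
    x = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
    coef, *_ = np.linalg.lstsq(x, genewise[ok], rcond=None)
    a1, a0 = np.maximum(coef, 0.0)
    if a1 == 0.0 and a0 == 0.0:
        a1 = max(fallback, DISPERSION_FLOOR)
    with np.errstate(divide="ignore"):
        trend = a1 + a0 / np.where(mean > 0, mean, np.nan)
    trend = np.where(np.isfinite(trend), trend, a1 if a1 > 0 else fallback)
    return np.maximum(trend, DISPERSION_FLOOR)


# ---------------------------------------------------------------------------
# Multiple testing


def adjust_bh(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are excluded from the ranking (and from m) and propagate
    as NaN.
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    if m == 0:
        return out
    vals = p[ok]
    order = np.argsort(vals, kind="mergesort")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


# ---------------------------------------------------------------------------
# Differential TE test


def _cell_stats(norm: pd.DataFrame, factors: pd.Series, cols: pd.Index,
                dispersion: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """MLE cell mean (arithmetic mean of normalized counts) and the
    delta-method variance of its log for every gene.

    Var(log t) = (sum_i 1/s_i) / (m^2 t) + dispersion / m, from
    Var(y_i / s_i) = t / s_i + dispersion * t^2.
    """
    sub = norm[cols].to_numpy(dtype=float)
    s = factors.loc[cols].to_numpy(dtype=float)
    m = len(cols)
    t = sub.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_log = (1.0 / s).sum() / (m**2 * t) + dispersion / m
    return t, var_log


def test_delta_te(rp: CountMatrix, rna: CountMatrix,
                  rp_dispersion: pd.Series | None = None,
                  rna_dispersion: pd.Series | None = None,
                  shrinkage_weight: float = 0.7,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene Wald test of the assay x condition interaction (delta TE_rel).

    ``log2_dte`` is the interaction coefficient in log2 units: positive
    means the gene's TE_rel rises in the mutant relative to the mRNA
    population. Size factors are estimated per assay (median-of-ratios);
    dispersions default to :func:`estimate_dispersion` per assay.
    Genes with an empty design cell do not converge and get missing
    statistics. BH adjustment runs over all converged genes.
    """
    genes = rp.counts.index.intersection(rna.counts.index)
    if len(genes) == 0:
        raise ValueError("no shared genes between RP and RNA matrices")
    rp = rp.subset_genes(genes)
    rna = rna.subset_genes(genes)

    results = {"base_mean": np.zeros(len(genes))}
    cell_means: dict[tuple[str, str], np.ndarray] = {}
    cell_vars: dict[tuple[str, str], np.ndarray] = {}
    for assay, cm, disp in (("RP", rp, rp_dispersion), ("RNA", rna, rna_dispersion)):
        factors = size_factors(cm.counts)
        if disp is None:
            disp = estimate_dispersion(cm, factors, shrinkage_weight)["dispersion"]
        disp_arr = disp.loc[genes].to_numpy(dtype=float)
        norm = normalize(cm.counts, factors)
        meta = cm.samples.loc[list(cm.counts.columns)]
        for cond in ("WT", "MUT"):
            cols = meta.index[(meta["assay"] == assay) & (meta["condition"] == cond)]
            if len(cols) < 2:
                raise ValueError(f"need >= 2 replicates for {assay}/{cond}")
            t, v = _cell_stats(norm, factors, cols, disp_arr)
            cell_means[(assay, cond)] = t
            cell_vars[(assay, cond)] = v
    results["base_mean"] = np.mean(
        [cell_means[k] for k in cell_means], axis=0)

    converged = np.ones(len(genes), dtype=bool)
    for key in cell_means:
        converged &= cell_means[key] > 0
    n_fail = int((~converged).sum())
    if n_fail:
        logger.info("test_delta_te: %d gene(s) with an empty design cell "
                    "(no convergence)", n_fail)

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (
            np.log(cell_means[("RP", "MUT")]) - np.log(cell_means[("RP", "WT")])
            - np.log(cell_means[("RNA", "MUT")]) + np.log(cell_means[("RNA", "WT")])
        )
        var = sum(cell_vars[k] for k in cell_vars)
    beta = np.where(converged, beta, np.nan)
    se = np.where(converged, np.sqrt(var), np.nan)
    wald = beta / se
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p = np.where(converged, p, np.nan)

    out = pd.DataFrame(
        {
            "base_mean": results["base_mean"],
            "log2_dte": beta / LN2,
            "se": se / LN2,
            "wald_stat": wald,
            "p": p,
            "converged": converged,
        },
        index=genes,
    )
    out["padj"] = adjust_bh(out["p"].to_numpy())
    out["category"] = [
        classify_te_change(lfc, padj, alpha=alpha)
        for lfc, padj in zip(out["log2_dte"], out["padj"])
    ]
    out.index.name = "gene_id"
    return out


def classify_te_change(log2_dte: float, padj: float, alpha: float = 0.05,
                       fold50: float = 1.5, fold100: float = 2.0) -> str:
    """Fold-change category for a significant TE change.

    Significant (padj < alpha) genes: ratio >= 2 -> ``up100``; >= 1.5 ->
    ``up50``; <= 1/2 -> ``down100``; <= 1/1.5 -> ``down50``; otherwise
    ``sig_small``. Non-significant or untested genes -> ``ns``.
    """
    if not np.isfinite(padj) or not np.isfinite(log2_dte) or padj >= alpha:
        return "ns"
    ratio = 2.0 ** log2_dte
    if ratio >= fold100:
        return "up100"
    if ratio >= fold50:
        return "up50"
    if ratio <= 1.0 / fold100:
        return "down100"
    if ratio <= 1.0 / fold50:
        return "down50"
    return "sig_small"
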