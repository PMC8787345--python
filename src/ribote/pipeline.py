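"""End-to-end orchestration: simulate -> quantify -> diffte -> features -> assoc.

Every run emits a manifest (config hash, seed, versions, per-stage record
counts, including how many records each exclusion rule dropped) and, for
simulated runs, a truth-vs-estimate evaluation.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, annotation_io, assoc, diffte, features, quantify
from .simulate import EffectModel, SimConfig, SimCounts, TruthTable, generate_counts, generate_transcriptome

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    outdir: str
    sim: SimConfig
    padj_alpha: float = 0.05
    rna_filter: int = 128
    fold50: float = 1.5
    fold100: float = 2.0

    def __post_init__(self) -> None:
        if min(self.padj_alpha, self.rna_filter, self.fold50, self.fold100) <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim_raw = dict(raw.pop("sim"))
        if "effect_model" in sim_raw:
            sim_raw["effect_model"] = EffectModel(**sim_raw["effect_model"])
        for key in ("tl_length_dist", "cds_codons_dist", "mean_expression_dist",
                    "pars_baseline", "structured_amplitude", "size_factor_range"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        return cls(sim=SimConfig(**sim_raw), **raw)

    def digest(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_simulated_inputs(outdir: Path, ann, sequences, tracks, isoforms,
                           truth: TruthTable, counts: SimCounts) -> None:
    """Persist simulator outputs in their external text formats."""
    outdir.mkdir(parents=True, exist_ok=True)
    annotation_io.write_annotation(ann, outdir / "annotation.gff3")
    annotation_io.write_fasta(sequences, outdir / "transcripts.fa")
    annotation_io.write_pars(tracks, outdir / "pars.bedgraph")
    annotation_io.write_isoforms(isoforms, outdir / "isoforms.tsv")
    truth.genes.to_csv(outdir / "truth.tsv", sep="\t", index_label="gene_id")
    annotation_io.write_position_counts(counts.position_counts,
                                        outdir / "rp_positions.tsv")
    annotation_io.write_counts(counts.rna, outdir / "rna_counts.tsv",
                               outdir / "samples.tsv")
    counts.size_factors.to_frame().to_csv(outdir / "true_size_factors.tsv", sep="\t",
                                          index_label="sample_id")


def run_full(config: RunConfig) -> dict:
    """Run the whole pipeline on simulated data; returns the result bundle.

    Any stage failure aborts with the stage name; partial outputs stay on
    disk next to a ``failed/<stage>`` marker.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.digest(),
        "seed": config.sim.seed,
        "version": __version__,
        "stages": {},
    }
    stage = "simulate"
    try:
        ann, sequences, tracks, isoforms, truth = generate_transcriptome(config.sim)
        counts = generate_counts(truth, config.sim)
        write_simulated_inputs(outdir / "inputs", ann, sequences, tracks,
                               isoforms, truth, counts)
        manifest["stages"]["simulate"] = {
            "n_genes": len(truth.genes),
            "n_samples": len(counts.samples),
            "n_position_records": len(counts.position_counts),
        }

        stage = "quantify"
        rp = quantify.count_cds(counts.position_counts, ann, counts.samples)
        rp = diffte_select(rp, assay="RP")
        uorf_rp = quantify.count_uorf(counts.position_counts, ann, counts.samples)
        kept = quantify.filter_low_expression(counts.rna, config.rna_filter)
        n_window_dropped = len(truth.genes) - len(rp.counts)
        manifest["stages"]["quantify"] = {
            "n_genes_countable": len(rp.counts),
            "dropped_empty_window": n_window_dropped,
            "n_uorfs": len(uorf_rp.counts),
            "kept_after_rna_filter": len(kept),
            "dropped_by_rna_filter": len(rp.counts.index.intersection(counts.rna.counts.index)) - len(kept),
        }

        stage = "diffte"
        genes = rp.counts.index.intersection(kept)
        te = diffte.test_delta_te(
            rp.subset_genes(genes),
            counts.rna.subset_genes(genes),
            alpha=config.padj_alpha,
        )
        te.to_csv(outdir / "te_results.tsv", sep="\t")
        manifest["stages"]["diffte"] = {
            "n_tested": len(te),
            "n_converged": int(te["converged"].sum()),
            "n_significant": int((te["padj"] < config.padj_alpha).sum()),
        }

        stage = "features"
        dominant = annotation_io.select_dominant_isoform(isoforms)
        feats = features.build_feature_table(ann, sequences, pars=tracks,
                                             dominant_tl=dominant)
        feats.to_csv(outdir / "features.tsv", sep="\t")
        manifest["stages"]["features"] = {
            "n_genes": len(feats),
            "n_with_dominant_isoform": int(feats["tl_length"].notna().sum()),
            "dropped_by_dominance_rule": int(feats["tl_length"].isna().sum()),
        }

        stage = "assoc"
        report = association_report(te, feats, alpha=config.padj_alpha)
        report.to_csv(outdir / "assoc_report.tsv", sep="\t", index=False)
        manifest["stages"]["assoc"] = {"n_analyses": len(report)}

        stage = "evaluate"
        evaluation = evaluate_against_truth(te, truth, alpha=config.padj_alpha)
        pd.Series(evaluation).to_frame("value").to_csv(
            outdir / "evaluation.tsv", sep="\t", index_label="metric")
        manifest["stages"]["evaluate"] = {"n_metrics": len(evaluation)}
    except Exception as exc:
        marker = outdir / "failed"
        marker.mkdir(exist_ok=True)
        (marker / stage).write_text(str(exc))
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {"te": te, "features": feats, "assoc": report,
            "evaluation": evaluation, "truth": truth, "manifest": manifest}


def diffte_select(cm, assay: str):
    """Restrict a count matrix to one assay's columns."""
    return cm.select(assay=assay)


def association_report(te: pd.DataFrame, feats: pd.DataFrame,
                       alpha: float = 0.05) -> pd.DataFrame:
    """The figure-level statistics: feature correlations with delta-TE and
    the decreased-vs-unchanged TL length contrast."""
    shared = te.index.intersection(feats.index)
    te = te.loc[shared]
    feats = feats.loc[shared]
    rows = []
    for feat, method in (("tl_length", "spearman"),
                         ("pars_max30", "spearman"),
                         ("pars_utr_all", "spearman"),
                         ("context_score", "spearman"),
                         ("cds_length", "spearman"),
                         ("transcript_length", "spearman")):
        x = feats[feat].to_numpy(dtype=float)
        y = te["log2_dte"].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            continue
        res = assoc.correlate(x[ok], y[ok], method=method)
        rows.append({"analysis": f"corr_dte_vs_{feat}", "statistic": res.rho,
                     "p": res.p, "n": res.n})

    sig_down = te.index[(te["padj"] < alpha) & (te["log2_dte"] < 0)]
    ns = te.index[~(te["padj"] < alpha)]
    tl = feats["tl_length"]
    down_vals = tl.loc[sig_down].dropna()
    ns_vals = tl.loc[ns].dropna()
    if len(down_vals) >= 3 and len(ns_vals) >= 3:
        res = assoc.compare_two_groups(
            np.concatenate([down_vals, ns_vals]),
            np.array(["down"] * len(down_vals) + ["ns"] * len(ns_vals)),
        )
        rows.append({
            "analysis": "wilcoxon_tl_down_vs_ns",
            "statistic": float(np.median(down_vals) - np.median(ns_vals)),
            "p": res.p, "n": len(down_vals) + len(ns_vals),
        })
    return pd.DataFrame(rows)


def evaluate_against_truth(te: pd.DataFrame, truth: TruthTable,
                           alpha: float = 0.05) -> dict:
    """Truth-vs-estimate metrics for a simulated run."""
    missing = te.index.difference(truth.genes.index)
    if len(missing) > 0:
        raise ValueError(f"tested genes absent from truth: {list(missing)[:5]}")
    t = truth.genes.loc[te.index]
    est = te["log2_dte"]
    ok = te["converged"] & est.notna()

    sig = ok & (te["padj"] < alpha)
    n_sig = int(sig.sum())
    n_false = int((sig & t["is_null"]).sum())
    metrics = {
        "n_tested": int(len(te)),
        "n_converged": int(ok.sum()),
        "n_significant": n_sig,
        "fdr_empirical": (n_false / n_sig) if n_sig else 0.0,
    }
    nonnull = ok & ~t["is_null"] & (t["true_log2_dte"] != 0)
    if nonnull.any():
        err = est[nonnull] - t.loc[nonnull, "true_log2_dte"]
        metrics["bias"] = float(err.mean())
        metrics["rmse"] = float(np.sqrt((err**2).mean()))
        metrics["sensitivity"] = float((sig & nonnull).sum() / nonnull.sum())
        for lo, hi in ((0.0, 0.5), (0.5, 1.0), (1.0, np.inf)):
            sel = nonnull & (t["true_log2_dte"].abs() > lo) & (t["true_log2_dte"].abs() <= hi)
            if sel.any():
                metrics[f"sensitivity_effect_{lo}_{hi}"] = float(
                    (sig & sel).sum() / sel.sum())
    corr = assoc.correlate(t.loc[ok, "true_log2_dte"], est[ok], method="spearman")
    metrics["spearman_true_vs_est"] = corr.rho
    return metrics
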