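"""Turn position-level footprint counts into filtered gene/uORF count matrices.

CDS counting excludes the first 15 and last 5 codons of every ORF to
avoid elongation-inhibitor edge artifacts; uORFs are counted full-length
because they are too short to trim. Genes with fewer than 128 total mRNA
reads across the four libraries of a strain pair are excluded before any
TE statistics.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .models import AnnotationSet, CountMatrix

logger = logging.getLogger(__name__)

CDS_SKIP_START_CODONS = 15
CDS_SKIP_END_CODONS = 5
DEFAULT_RNA_FILTER = 128


def cds_counting_window(cds_length_codons: int) -> tuple[int, int]:
    """0-based half-open codon interval retained for CDS counting.

    Returns ``[15, L - 5)``; empty (start >= end) when L <= 20, which marks
    the gene as not quantifiable.
    """
    if cds_length_codons < 1:
        raise ValueError("CDS must have at least one codon")
    start = CDS_SKIP_START_CODONS
    end = cds_length_codons - CDS_SKIP_END_CODONS
    if end <= start:
        return (start, start)
    return (start, end)


def _pivot_positions(pos: pd.DataFrame) -> pd.DataFrame:
    return pos.pivot_table(
        index=["transcript_id", "position"], columns="sample_id", values="count",
        aggfunc="sum", fill_value=0,
    )


def _validate_positions(pos: pd.DataFrame, ann: AnnotationSet) -> None:
    by_tid = {t.transcript_id: t for t in ann}
    lengths = pos.groupby("transcript_id")["position"].max()
    for tid, maxpos in lengths.items():
        if tid not in by_tid:
            raise ValueError(f"position counts reference unknown transcript {tid}")
        if maxpos >= by_tid[tid].transcript_length:
            raise ValueError(
                f"position {maxpos} outside transcript {tid} "
                f"(length {by_tid[tid].transcript_length})"
            )


def count_cds(pos: pd.DataFrame, ann: AnnotationSet, samples: pd.DataFrame) -> CountMatrix:
    """Sum footprint counts over each gene's CDS counting window.

    A nt position maps to codon ``floor((p - cds_start) / 3)``; only codons
    inside :func:`cds_counting_window` contribute. Genes whose window is
    empty are dropped (and logged).
    """
    _validate_positions(pos, ann)
    sample_ids = list(samples.index)
    wide = _pivot_positions(pos)
    rows = {}
    n_dropped = 0
    for t in ann:
        win_start, win_end = cds_counting_window(t.cds_length_codons)
        if win_end <= win_start:
            n_dropped += 1
            logger.info("gene %s dropped: CDS of %d codons has empty counting window",
                        t.gene_id, t.cds_length_codons)
            continue
        lo = t.cds_start + 3 * win_start
        hi = t.cds_start + 3 * win_end
        if t.transcript_id in wide.index.get_level_values(0):
            block = wide.loc[t.transcript_id]
            sel = block[(block.index >= lo) & (block.index < hi)]
            sums = sel.sum(axis=0)
        else:
            sums = pd.Series(0, index=wide.columns)
        rows[t.gene_id] = [int(sums.get(s, 0)) for s in sample_ids]
    if n_dropped:
        logger.info("count_cds: dropped %d gene(s) with empty counting windows", n_dropped)
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    counts.index.name = "gene_id"
    return CountMatrix(counts.sort_index(), samples)


def count_uorf(pos: pd.DataFrame, ann: AnnotationSet, samples: pd.DataFrame) -> CountMatrix:
    """Sum footprint counts over each annotated uORF, full length, no trimming."""
    _validate_positions(pos, ann)
    sample_ids = list(samples.index)
    wide = _pivot_positions(pos)
    rows = {}
    for t in ann:
        has_data = t.transcript_id in wide.index.get_level_values(0)
        block = wide.loc[t.transcript_id] if has_data else None
        for u in t.uorfs:
            if block is not None:
                sel = block[(block.index >= u.start) & (block.index < u.end)]
                sums = sel.sum(axis=0)
            else:
                sums = pd.Series(0, index=wide.columns)
            rows[u.uorf_id] = [int(sums.get(s, 0)) for s in sample_ids]
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    if counts.empty:
        counts = pd.DataFrame(columns=sample_ids, dtype=np.int64)
    counts.index.name = "uorf_id"
    return CountMatrix(counts.sort_index(), samples)


def filter_low_expression(rna: CountMatrix, threshold: int = DEFAULT_RNA_FILTER) -> pd.Index:
    """Genes whose total mRNA count over the strain pair's four libraries
    reaches ``threshold``.

    Requires exactly the four RNA samples of one strain pair (2 WT + 2 MUT);
    a gene is kept iff its combined total is >= threshold (a total of
    exactly 128 is not "fewer than 128" and is kept).
    """
    meta = rna.samples.loc[list(rna.counts.columns)]
    if not (meta["assay"] == "RNA").all():
        raise ValueError("filter_low_expression expects RNA samples only")
    n_wt = int((meta["condition"] == "WT").sum())
    n_mut = int((meta["condition"] == "MUT").sum())
    if len(meta) != 4 or n_wt != 2 or n_mut != 2:
        raise ValueError(
            f"filter expects the 4 RNA libraries of one strain pair "
            f"(2 WT + 2 MUT); got {n_wt} WT + {n_mut} MUT"
        )
    totals = rna.counts.sum(axis=1)
    kept = rna.counts.index[totals >= threshold]
    logger.info("expression filter: kept %d / %d genes (threshold %d)",
                len(kept), len(totals), threshold)
    return kept
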