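"""Readers/writers for annotation, sequence, structure-track and table formats.

GFF3 files produced and consumed here describe transcript models in
*transcript* coordinates: the seqid column is the transcript id and
positions are 1-based inclusive along the transcript, per the GFF3
standard. The internal representation is 0-based half-open
(see :mod:`ribote.models`). bedGraph tracks are 0-based half-open.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import CLOSED_LOOP_GROUPS, AnnotationSet, CountMatrix, TranscriptModel, UorfModel

logger = logging.getLogger(__name__)

_GFF_COLS = 9
_COORD_PRAGMA = "#!coordinate-frame transcript"


class SchemaError(ValueError):
    """A file violates its declared column schema."""


# ---------------------------------------------------------------------------
# GFF3


def write_annotation(ann: AnnotationSet, path: str | Path) -> None:
    """Write transcript models as GFF3 (1-based inclusive, transcript frame)."""
    lines = ["##gff-version 3", _COORD_PRAGMA]
    for gene_id in sorted(ann.transcripts):
        t = ann.transcripts[gene_id]
        tid = t.transcript_id
        lines.append(
            f"{tid}\tribote\ttranscript\t1\t{t.transcript_length}\t.\t+\t.\t"
            f"ID={tid};gene_id={gene_id}"
        )
        lines.append(
            f"{tid}\tribote\tCDS\t{t.cds_start + 1}\t{t.cds_end}\t.\t+\t0\t"
            f"ID={tid}.cds;Parent={tid}"
        )
        for u in t.uorfs:
            lines.append(
                f"{tid}\tribote\tuORF\t{u.start + 1}\t{u.start + u.length}\t.\t+\t0\t"
                f"ID={u.uorf_id};Parent={tid};start_codon={u.start_codon}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attributes(field: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in field.rstrip(";").split(";"):
        if not item:
            continue
        if "=" not in item:
            raise ValueError(f"malformed attribute {item!r}")
        key, value = item.split("=", 1)
        out[key] = value
    return out


def read_annotation(path: str | Path) -> AnnotationSet:
    """Parse a transcript-frame GFF3 into an :class:`AnnotationSet`.

    Malformed lines raise with the 1-based line number. Transcripts whose
    CDS length is not a multiple of 3 are rejected and logged, not fatal.
    """
    spans: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _GFF_COLS:
                raise ValueError(
                    f"{path}:{lineno}: expected {_GFF_COLS} tab-separated fields, "
                    f"got {len(fields)}"
                )
            seqid, _source, ftype, start_s, end_s, _score, _strand, _frame, attrs_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
                attrs = _parse_attributes(attrs_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if start1 < 1 or end1 < start1:
                raise ValueError(f"{path}:{lineno}: invalid interval {start1}..{end1}")
            # GFF3 1-based inclusive -> internal 0-based half-open
            start, end = start1 - 1, end1
            rec = spans.setdefault(seqid, {"uorfs": []})
            if ftype == "transcript":
                rec["gene_id"] = attrs.get("gene_id", seqid)
                rec["length"] = end - start
            elif ftype == "CDS":
                rec["cds_start"] = start
                rec["cds_end"] = end
            elif ftype == "uORF":
                rec["uorfs"].append(
                    (attrs.get("ID", f"{seqid}.uorf{len(rec['uorfs'])}"),
                     start, end - start, attrs.get("start_codon", "ATG"))
                )
            # other feature types are ignored

    transcripts: dict[str, TranscriptModel] = {}
    for tid, rec in spans.items():
        if "length" not in rec or "cds_start" not in rec:
            logger.warning("transcript %s lacks transcript/CDS features; skipped", tid)
            continue
        cds_len = rec["cds_end"] - rec["cds_start"]
        if cds_len % 3 != 0:
            logger.warning(
                "transcript %s rejected: CDS length %d not divisible by 3", tid, cds_len
            )
            continue
        try:
            model = TranscriptModel(
                gene_id=rec["gene_id"],
                transcript_id=tid,
                tl_length=rec["cds_start"],
                cds_length=cds_len,
                transcript_length=rec["length"],
                uorfs=tuple(
                    UorfModel(uorf_id=u[0], start=u[1], length=u[2], start_codon=u[3])
                    for u in rec["uorfs"]
                ),
            )
        except ValueError as exc:
            logger.warning("transcript %s rejected: %s", tid, exc)
            continue
        transcripts[model.gene_id] = model
    return AnnotationSet(transcripts)


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sorted(seqs.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# bedGraph (PARS tracks)


def write_pars(tracks: dict[str, np.ndarray], path: str | Path) -> None:
    """Write per-nt tracks as bedGraph; NaN runs are simply omitted."""
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="PARS"\n')
        for tid in sorted(tracks):
            values = np.asarray(tracks[tid], dtype=float)
            i = 0
            n = len(values)
            while i < n:
                if np.isnan(values[i]):
                    i += 1
                    continue
                j = i + 1
                while j < n and not np.isnan(values[j]) and values[j] == values[i]:
                    j += 1
                fh.write(f"{tid}\t{i}\t{j}\t{float(values[i])!r}\n")
                i = j


def read_pars(path: str | Path, lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Expand a bedGraph into per-nt vectors; uncovered nts are NaN.

    ``lengths`` maps transcript id -> transcript length and fixes the
    output vector lengths; intervals beyond a declared length are an error.
    """
    tracks = {tid: np.full(n, np.nan) for tid, n in lengths.items()}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise SchemaError(f"{path}:{lineno}: bedGraph needs 4 columns")
            tid, start_s, end_s, value_s = fields
            start, end, value = int(start_s), int(end_s), float(value_s)
            if tid not in tracks:
                logger.warning("%s:%d: unknown transcript %s; ignored", path, lineno, tid)
                continue
            if end > len(tracks[tid]) or start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: interval [{start},{end}) outside transcript "
                    f"{tid} of length {len(tracks[tid])}"
                )
            tracks[tid][start:end] = value
    return tracks


# ---------------------------------------------------------------------------
# TSV tables


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing mandatory column(s) {missing}")


def write_isoforms(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_isoforms(path: str | Path) -> pd.DataFrame:
    """Isoform table: gene_id, isoform_id, tl_length, relative_abundance."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene_id", "isoform_id", "tl_length", "relative_abundance"],
                     "isoform table")
    if (df["relative_abundance"] < 0).any():
        raise ValueError("isoform table: negative abundances")
    sums = df.groupby("gene_id")["relative_abundance"].sum()
    over = sums[sums > 1 + 1e-6]
    if not over.empty:
        raise ValueError(
            f"isoform table: abundances of {list(over.index[:5])} sum above 1"
        )
    return df


def select_dominant_isoform(table: pd.DataFrame) -> dict[str, int | None]:
    """Apply the 40%/2x dominance rule per gene.

    Abundances are renormalized to sum to 1 within each gene, then the top
    isoform is dominant iff its fraction is >= 0.40 AND >= 2x the second
    most abundant one (ties at the thresholds pass). Single-isoform genes
    pass iff their (renormalized) fraction >= 0.40, which is always true
    after renormalization unless the abundance is zero. Failing genes map
    to ``None``.
    """
    out: dict[str, int | None] = {}
    for gene_id, grp in table.groupby("gene_id", sort=False):
        ab = grp["relative_abundance"].to_numpy(dtype=float)
        total = ab.sum()
        if total <= 0:
            out[gene_id] = None
            continue
        frac = ab / total
        order = np.argsort(frac)[::-1]
        top = frac[order[0]]
        second = frac[order[1]] if len(frac) > 1 else 0.0
        if top >= 0.40 and top >= 2.0 * second:
            out[gene_id] = int(grp["tl_length"].to_numpy()[order[0]])
        else:
            out[gene_id] = None
    return out


def write_counts(cm: CountMatrix, counts_path: str | Path, samples_path: str | Path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    cm.samples.to_csv(samples_path, sep="\t", index_label="sample_id")


def read_counts(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    _require_columns(samples.reset_index(), ["sample_id", "assay", "condition", "replicate"],
                     "sample table")
    return CountMatrix(counts.astype(np.int64), samples)


def write_position_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_position_counts(path: str | Path) -> pd.DataFrame:
    """Long table of footprint counts: transcript_id, position, sample_id, count."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["transcript_id", "position", "sample_id", "count"],
                     "position counts")
    if (df["count"] < 0).any() or (df["position"] < 0).any():
        raise ValueError("position counts: negative position or count")
    return df


def read_closed_loop(path: str | Path) -> dict[str, int]:
    """Closed-loop group assignments: gene_id, group (1-4)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene_id", "group"], "closed-loop table")
    bad = set(df["group"].astype(int)) - CLOSED_LOOP_GROUPS
    if bad:
        raise ValueError(f"closed-loop table: invalid group label(s) {sorted(bad)}")
    return dict(zip(df["gene_id"], df["group"].astype(int)))


def read_external_dte(path: str | Path) -> pd.DataFrame:
    """External delta-TE table: gene_id, log2_dte[, padj]. Duplicates: last wins."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene_id", "log2_dte"], "external delta-TE table")
    dup = df["gene_id"].duplicated(keep=False)
    if dup.any():
        logger.warning(
            "external delta-TE table %s: %d duplicate gene id(s); keeping last",
            path, df.loc[dup, "gene_id"].nunique(),
        )
        df = df.drop_duplicates("gene_id", keep="last")
    return df.set_index("gene_id")
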