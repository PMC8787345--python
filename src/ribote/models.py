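"""Core domain types shared across the package.

Coordinate convention: all internal coordinates are 0-based, half-open,
in the transcript frame (5' end of the transcript = position 0). GFF3
I/O converts to/from the 1-based inclusive convention of that format.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

VALID_ASSAYS = frozenset({"RP", "RNA"})
VALID_CONDITIONS = frozenset({"WT", "MUT"})
CLOSED_LOOP_GROUPS = frozenset({1, 2, 3, 4})


@dataclass(frozen=True)
class UorfModel:
    """An upstream ORF located within the transcript leader.

    ``start`` is the 0-based nt offset of the uORF start codon from the
    transcript 5' end; ``length`` spans start codon through stop, in nt.
    """

    uorf_id: str
    start: int
    length: int
    start_codon: str = "ATG"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"uORF {self.uorf_id}: negative start {self.start}")
        if self.length < 3:
            raise ValueError(f"uORF {self.uorf_id}: length {self.length} < 3")
        if self.length % 3 != 0:
            raise ValueError(
                f"uORF {self.uorf_id}: length {self.length} not a multiple of 3"
            )
        if len(self.start_codon) != 3:
            raise ValueError(f"uORF {self.uorf_id}: start codon must be a 3-mer")

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class TranscriptModel:
    """Geometry of one gene's (dominant) transcript in transcript coordinates.

    The CDS starts exactly where the transcript leader ends
    (``cds_start == tl_length``); anything past the stop codon is the
    3' trailer.
    """

    gene_id: str
    transcript_id: str
    tl_length: int
    cds_length: int
    transcript_length: int
    uorfs: tuple[UorfModel, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.tl_length < 0:
            raise ValueError(f"{self.transcript_id}: negative TL length")
        if self.cds_length < 3 or self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.cds_length} "
                "must be a positive multiple of 3"
            )
        if self.tl_length + self.cds_length > self.transcript_length:
            raise ValueError(
                f"{self.transcript_id}: TL + CDS ({self.tl_length + self.cds_length}) "
                f"exceeds transcript length {self.transcript_length}"
            )
        for u in self.uorfs:
            if u.start >= self.tl_length:
                raise ValueError(
                    f"uORF {u.uorf_id} of {self.transcript_id} starts at {u.start}, "
                    f"outside the TL [0, {self.tl_length})"
                )
            if u.end > self.tl_length:
                raise ValueError(
                    f"uORF {u.uorf_id} of {self.transcript_id} extends to {u.end}, "
                    f"past the TL end at {self.tl_length}"
                )

    @property
    def cds_start(self) -> int:
        return self.tl_length

    @property
    def cds_end(self) -> int:
        return self.tl_length + self.cds_length

    @property
    def cds_length_codons(self) -> int:
        return self.cds_length // 3


@dataclass
class AnnotationSet:
    """One transcript model per gene, keyed by gene id."""

    transcripts: dict[str, TranscriptModel]

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts.values())

    def __getitem__(self, gene_id: str) -> TranscriptModel:
        return self.transcripts[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.transcripts

    def by_transcript(self) -> dict[str, TranscriptModel]:
        return {t.transcript_id: t for t in self}


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with sample metadata.

    ``counts``: DataFrame indexed by gene id, columns = sample ids.
    ``samples``: DataFrame indexed by sample id with columns
    ``assay`` (RP|RNA), ``condition`` (WT|MUT), ``replicate`` (int).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)}")
        required = {"assay", "condition", "replicate"}
        if not required <= set(self.samples.columns):
            raise ValueError(f"sample table needs columns {sorted(required)}")
        bad_assay = set(self.samples["assay"]) - VALID_ASSAYS
        if bad_assay:
            raise ValueError(f"unknown assay values: {sorted(bad_assay)}")
        bad_cond = set(self.samples["condition"]) - VALID_CONDITIONS
        if bad_cond:
            raise ValueError(f"unknown condition values: {sorted(bad_cond)}")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)], self.samples)

    def select(self, assay: str | None = None, condition: str | None = None) -> "CountMatrix":
        meta = self.samples.loc[list(self.counts.columns)]
        mask = pd.Series(True, index=meta.index)
        if assay is not None:
            mask &= meta["assay"] == assay
        if condition is not None:
            mask &= meta["condition"] == condition
        cols = meta.index[mask]
        return CountMatrix(self.counts[cols], self.samples)
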