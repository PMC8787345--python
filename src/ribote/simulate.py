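"""Ground-truth simulator for the whole analysis chain.

Generates transcript annotation, sequences, per-nt structure tracks,
isoform-abundance tables and paired footprint/mRNA count data with a
known truth table, so every downstream rule and statistic is testable
against planted values.

Counts are generated at codon resolution in transcript coordinates: no
reads, no alignment. NB parameterization everywhere:
``variance = mean + dispersion * mean**2`` (dispersion -> 0 is Poisson).
Library size factors are planted per sample (log-uniform in a configured
range by default) so normalization recovery is testable. The optional
5'-ramp artifact *adds* extra footprints within the first 15 codons from
an independent random stream, leaving all other draws untouched, so the
codon-exclusion rule must remove its effect exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation_io import select_dominant_isoform
from .models import AnnotationSet, CountMatrix, TranscriptModel, UorfModel

CONTEXT_CONSENSUS = "AAAAAA" + "ATG" + "T"  # nt -6..+4, A-rich upstream
RAMP_CODONS = 15


@dataclass(frozen=True)
class EffectModel:
    """Linear model linking true log2 delta-TE to (centered) gene features."""

    utr_length: float = 0.0      # per nt of TL
    max30: float = 0.0           # per PARS unit
    context_score: float = 0.0   # per unit of context strength in [0, 1]
    noise_sd: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    n_genes: int
    n_replicates: int = 2
    seed: int = 0
    # geometry
    tl_length_dist: tuple[float, float] = (4.5, 0.6)       # lognormal (mu, sigma), nt
    cds_codons_dist: tuple[float, float] = (5.0, 0.4)      # lognormal, codons
    min_cds_codons: int = 25
    trailer_length: int = 60
    uorf_rate: float = 0.3
    frac_dominant: float = 0.8
    # expression
    mean_expression_dist: tuple[float, float] = (5.5, 1.0)  # lognormal, counts
    te_sd_log: float = 0.3
    rp_depth: float = 1.0
    # dispersion = a1 + a0 / mean
    dispersion_a0: float = 1.0
    dispersion_a1: float = 0.02
    # structure track
    pars_baseline: tuple[float, float] = (-0.5, 0.8)        # normal (mu, sd)
    structured_frac: float = 0.5
    structured_amplitude: tuple[float, float] = (1.0, 3.0)
    # effects
    effect_model: EffectModel = field(default_factory=EffectModel)
    frac_null: float = 0.5
    # libraries
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    size_factors: dict[str, float] | None = None
    ramp: bool = False
    ramp_excess: float = 2.0     # extra footprints per ramp codon, x uniform rate
    uorf_te_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError(
                f"n_genes={self.n_genes} is too small: downstream dispersion "
                "trends and FDR statistics need at least 10 genes"
            )
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")
        if not 0.0 <= self.frac_null <= 1.0:
            raise ValueError("frac_null must be in [0, 1]")
        if not 0.0 <= self.frac_dominant <= 1.0:
            raise ValueError("frac_dominant must be in [0, 1]")
        for name in ("tl_length_dist", "cds_codons_dist", "mean_expression_dist"):
            if not all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} parameters must be finite")


@dataclass
class TruthTable:
    """Planted per-gene ground truth plus the generating annotation."""

    genes: pd.DataFrame
    annotation: AnnotationSet

    def __post_init__(self) -> None:
        g = self.genes
        if (g.loc[g["is_null"], "true_log2_dte"] != 0).any():
            raise ValueError("null genes must have true_log2_dte == 0")
        if (g[["dispersion_rp", "dispersion_rna"]] <= 0).any().any():
            raise ValueError("dispersions must be positive")


@dataclass
class SimCounts:
    """Position-level footprint counts plus the gene-level RNA matrix."""

    position_counts: pd.DataFrame   # transcript_id, position, sample_id, count
    rna: CountMatrix
    samples: pd.DataFrame           # metadata for all RP + RNA samples
    size_factors: pd.Series         # planted truth, per sample


def _max30_of(track: np.ndarray, tl: int) -> float:
    """Max over all 30-nt window means inside the TL, via cumulative sums
    (independent of the feature module's sliding-window implementation)."""
    if tl < 30:
        return np.nan
    csum = np.concatenate([[0.0], np.cumsum(track[:tl])])
    sums = csum[30:] - csum[:-30]
    return float(sums.max() / 30.0)


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(np.array(list("ACGT")), size=n)


def generate_transcriptome(config: SimConfig):
    """Generate annotation, sequences, PARS tracks, isoforms and truth.

    Returns ``(annotation, sequences, pars_tracks, isoform_table, truth)``.
    Deterministic for a given config (seeded from ``config.seed``).
    """
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]

    mu_tl, sd_tl = config.tl_length_dist
    tl_lengths = np.maximum(10, rng.lognormal(mu_tl, sd_tl, n).astype(int))
    mu_c, sd_c = config.cds_codons_dist
    cds_codons = np.maximum(config.min_cds_codons,
                            rng.lognormal(mu_c, sd_c, n).astype(int))
    context_strength = rng.beta(2.0, 2.0, n)

    n_dominant = int(round(config.frac_dominant * n))
    dominant_flags = np.zeros(n, dtype=bool)
    dominant_flags[rng.permutation(n)[:n_dominant]] = True

    transcripts: dict[str, TranscriptModel] = {}
    sequences: dict[str, str] = {}
    tracks: dict[str, np.ndarray] = {}
    iso_rows = []
    truth_rows = []

    for i, gene in enumerate(gene_ids):
        tl = int(tl_lengths[i])
        cds_len = int(cds_codons[i]) * 3
        tx_len = tl + cds_len + config.trailer_length
        tid = f"{gene}.t1"

        # --- uORFs, fully inside the TL
        uorfs = []
        for k in range(rng.poisson(config.uorf_rate)):
            max_codons = (tl - 1) // 3
            if max_codons < 2:
                break
            n_codons = int(rng.integers(2, min(max_codons, 12) + 1))
            start_max = tl - 3 * n_codons
            if start_max < 0:
                continue
            start = int(rng.integers(0, start_max + 1))
            uorfs.append(UorfModel(uorf_id=f"{tid}.uorf{len(uorfs) + 1}",
                                   start=start, length=3 * n_codons))
        model = TranscriptModel(gene_id=gene, transcript_id=tid, tl_length=tl,
                                cds_length=cds_len, transcript_length=tx_len,
                                uorfs=tuple(uorfs))
        transcripts[gene] = model

        # --- sequence with start codon and tunable -6..+4 context
        seq = _random_seq(rng, tx_len)
        ctx_draw = rng.random(10)
        rand_ctx = _random_seq(rng, 10)
        for j in range(10):
            pos = tl - 6 + j
            if 6 <= j <= 8:
                seq[pos] = CONTEXT_CONSENSUS[j]          # the AUG itself
            elif ctx_draw[j] < context_strength[i]:
                seq[pos] = CONTEXT_CONSENSUS[j]
            else:
                seq[pos] = rand_ctx[j]
        for u in uorfs:
            seq[u.start:u.start + 3] = list("ATG")
        sequences[tid] = "".join(seq)

        # --- PARS track with an optionally planted structured window
        mu_p, sd_p = config.pars_baseline
        track = rng.normal(mu_p, sd_p, tx_len)
        structured = rng.random() < config.structured_frac
        if structured and tl >= 30:
            w_start = int(rng.integers(0, tl - 30 + 1))
            lo, hi = config.structured_amplitude
            track[w_start:w_start + 30] += rng.uniform(lo, hi)
        tracks[tid] = track

        # --- isoform abundances obeying / violating the 40%/2x rule
        if dominant_flags[i]:
            top = float(rng.uniform(0.45, 0.85))
            rest = 1.0 - top
            # k chosen so even a 1.2/0.8-jittered minor stays below top/2
            k_minor = max(1, int(np.ceil(3.0 * rest / top)))
            raw = rng.uniform(0.8, 1.2, k_minor)
            minors = rest * raw / raw.sum()
            abundances = [top, *minors]
        else:
            top = float(rng.uniform(0.30, 0.48))
            second = float(rng.uniform(0.6, 1.0)) * top
            abundances = [top, second, 1.0 - top - second]
        tl_variants = [tl] + [
            max(5, tl + int(d)) for d in rng.integers(-40, 41, len(abundances) - 1)
        ]
        for j, (ab, tlj) in enumerate(zip(abundances, tl_variants), start=1):
            iso_rows.append({"gene_id": gene, "isoform_id": f"{gene}.iso{j}",
                            "tl_length": tlj, "relative_abundance": float(ab)})

        truth_rows.append({
            "gene_id": gene,
            "tl_length": tl,
            "cds_length": cds_len,
            "n_uorfs": len(uorfs),
            "context_strength": context_strength[i],
            "max30": _max30_of(track, tl),
            "has_dominant_isoform": bool(dominant_flags[i]),
        })

    isoforms = pd.DataFrame(iso_rows)
    ann = AnnotationSet(transcripts)

    # check the planted dominance pattern against the production rule
    dom = select_dominant_isoform(isoforms)
    planted = {r["gene_id"]: r["has_dominant_isoform"] for r in truth_rows}
    mismatch = [g for g in gene_ids if (dom[g] is not None) != planted[g]]
    if mismatch:  # pragma: no cover - generation bug guard
        raise AssertionError(f"dominance construction failed for {mismatch[:5]}")

    truth_df = pd.DataFrame(truth_rows).set_index("gene_id")

    # --- expression, dispersion and the planted effect
    mu_e, sd_e = config.mean_expression_dist
    truth_df["true_mean_rna"] = rng.lognormal(mu_e, sd_e, n)
    truth_df["true_te_wt"] = rng.lognormal(0.0, config.te_sd_log, n)
    mean_rp = truth_df["true_mean_rna"] * truth_df["true_te_wt"] * config.rp_depth
    truth_df["dispersion_rna"] = config.dispersion_a1 + config.dispersion_a0 / truth_df["true_mean_rna"]
    truth_df["dispersion_rp"] = config.dispersion_a1 + config.dispersion_a0 / mean_rp

    em = config.effect_model
    feats = pd.DataFrame({
        "utr_length": truth_df["tl_length"].astype(float),
        "max30": truth_df["max30"],
        "context_score": truth_df["context_strength"],
    })
    centered = feats.fillna(feats.mean()) - feats.mean()
    effect = (em.utr_length * centered["utr_length"]
              + em.max30 * centered["max30"]
              + em.context_score * centered["context_score"]).to_numpy()
    if em.noise_sd > 0:
        effect = effect + rng.normal(0.0, em.noise_sd, n)
    is_null = rng.random(n) < config.frac_null
    truth_df["is_null"] = is_null
    truth_df["true_log2_dte"] = np.where(is_null, 0.0, np.asarray(effect))

    truth = TruthTable(genes=truth_df, annotation=ann)
    return ann, sequences, tracks, isoforms, truth


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        raise ValueError("planted NB mean must be positive")
    if dispersion <= 1e-8:
        return int(rng.poisson(mean))
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return int(rng.poisson(lam))


def sample_table(n_replicates: int = 2) -> pd.DataFrame:
    rows = []
    for assay in ("RP", "RNA"):
        for cond in ("WT", "MUT"):
            for rep in range(1, n_replicates + 1):
                rows.append({"sample_id": f"{assay}_{cond}_{rep}",
                             "assay": assay, "condition": cond, "replicate": rep})
    return pd.DataFrame(rows).set_index("sample_id")


def generate_counts(truth: TruthTable, config: SimConfig) -> SimCounts:
    """Draw RNA and positional footprint counts from the planted truth.

    RNA: per gene and sample, NB(true_mean_rna x size factor, dispersion_rna).
    RP: a gene-level NB total (mean proportional to RNA mean x TE, with TE
    doubled/halved in the mutant per the planted log2 delta-TE) spread
    multinomially across CDS codons; each codon's count lands on its first
    nt. uORFs get occupancy the same way at a reduced rate. The optional
    5' ramp adds extra counts in the first 15 codons from a separate
    random stream, leaving all base draws identical to a ramp-off run.
    """
    rng = np.random.default_rng([config.seed, 1])
    ramp_rng = np.random.default_rng([config.seed, 2])
    samples = sample_table(config.n_replicates)

    if config.size_factors is not None:
        sf = pd.Series(config.size_factors).reindex(samples.index)
        if sf.isna().any():
            raise ValueError("size_factors must cover every sample")
    else:
        lo, hi = config.size_factor_range
        sf = pd.Series(np.exp(rng.uniform(np.log(lo), np.log(hi), len(samples))),
                       index=samples.index)
    sf.name = "size_factor"

    genes = truth.genes
    if (genes["true_mean_rna"] <= 0).any():
        raise ValueError("planted RNA means must be positive")

    rna_cols = [s for s in samples.index if samples.loc[s, "assay"] == "RNA"]
    rp_cols = [s for s in samples.index if samples.loc[s, "assay"] == "RP"]

    rna_mat = np.zeros((len(genes), len(rna_cols)), dtype=np.int64)
    pos_records: list[tuple[str, int, str, int]] = []

    for gi, (gene, row) in enumerate(genes.iterrows()):
        model = truth.annotation[gene]
        n_codons = model.cds_length_codons
        codon_pos = model.cds_start + 3 * np.arange(n_codons)

        for sj, s in enumerate(rna_cols):
            mean = row["true_mean_rna"] * sf[s]
            rna_mat[gi, sj] = _nb_draw(rng, mean, row["dispersion_rna"])

        for s in rp_cols:
            cond = samples.loc[s, "condition"]
            te = row["true_te_wt"]
            if cond == "MUT":
                te *= 2.0 ** row["true_log2_dte"]
            mean = row["true_mean_rna"] * te * config.rp_depth * sf[s]
            total = _nb_draw(rng, mean, row["dispersion_rp"])
            if total > 0:
                codon_counts = rng.multinomial(total, np.full(n_codons, 1.0 / n_codons))
            else:
                codon_counts = np.zeros(n_codons, dtype=np.int64)
            if config.ramp:
                k = min(RAMP_CODONS, n_codons)
                extra_mean = config.ramp_excess * mean / n_codons
                codon_counts = codon_counts.copy()
                codon_counts[:k] += ramp_rng.poisson(extra_mean, k)
            for pos, c in zip(codon_pos, codon_counts):
                if c > 0:
                    pos_records.append((model.transcript_id, int(pos), s, int(c)))

            for u in model.uorfs:
                u_mean = max(mean * config.uorf_te_scale, 1e-6)
                u_total = _nb_draw(rng, u_mean, row["dispersion_rp"])
                if u_total == 0:
                    continue
                n_uc = u.length // 3
                uc = rng.multinomial(u_total, np.full(n_uc, 1.0 / n_uc))
                for k, c in enumerate(uc):
                    if c > 0:
                        pos_records.append(
                            (model.transcript_id, int(u.start + 3 * k), s, int(c)))

    position_counts = pd.DataFrame(
        pos_records, columns=["transcript_id", "position", "sample_id", "count"])
    rna = CountMatrix(
        pd.DataFrame(rna_mat, index=genes.index, columns=rna_cols), samples)
    return SimCounts(position_counts=position_counts, rna=rna,
                     samples=samples, size_factors=sf)
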