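import numpy as np
import pandas as pd
import pytest

from ribote.models import AnnotationSet, CountMatrix, TranscriptModel, UorfModel
from ribote.simulate import EffectModel, SimConfig, generate_counts, generate_transcriptome


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared by read-only tests."""
    cfg = SimConfig(n_genes=120, seed=7, frac_null=0.5,
                    effect_model=EffectModel(utr_length=-0.004, noise_sd=0.2))
    ann, seqs, tracks, isoforms, truth = generate_transcriptome(cfg)
    counts = generate_counts(truth, cfg)
    return {"config": cfg, "annotation": ann, "sequences": seqs,
            "tracks": tracks, "isoforms": isoforms, "truth": truth,
            "counts": counts}


@pytest.fixture
def toy_annotation():
    """One gene: 50 nt TL, 100-codon CDS, one 9-nt uORF at position 10."""
    model = TranscriptModel(
        gene_id="gA", transcript_id="gA.t1", tl_length=50, cds_length=300,
        transcript_length=400,
        uorfs=(UorfModel(uorf_id="gA.t1.uorf1", start=10, length=9),),
    )
    return AnnotationSet({"gA": model})


@pytest.fixture
def sample_meta():
    rows = []
    for assay in ("RP", "RNA"):
        for cond in ("WT", "MUT"):
            for rep in (1, 2):
                rows.append({"sample_id": f"{assay}_{cond}_{rep}", "assay": assay,
                             "condition": cond, "replicate": rep})
    return pd.DataFrame(rows).set_index("sample_id")


def uniform_positions(model, samples, per_codon=1):
    """Position counts with `per_codon` footprints on every CDS codon."""
    rows = []
    for s in samples.index:
        if samples.loc[s, "assay"] != "RP":
            continue
        for k in range(model.cds_length_codons):
            rows.append({"transcript_id": model.transcript_id,
                         "position": model.cds_start + 3 * k,
                         "sample_id": s, "count": per_codon})
    return pd.DataFrame(rows)


@pytest.fixture
def rna_counts_factory(sample_meta):
    def make(totals_by_gene):
        rna_cols = [s for s in sample_meta.index if sample_meta.loc[s, "assay"] == "RNA"]
        data = {g: list(v) for g, v in totals_by_gene.items()}
        counts = pd.DataFrame.from_dict(data, orient="index", columns=rna_cols)
        counts.index.name = "gene_id"
        return CountMatrix(counts, sample_meta)
    return make
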