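# ribote

Differential translational-efficiency (TE) analysis for ribosome
profiling, with 5′-UTR feature scoring and a ground-truth simulator.

Given position-level ribosome-footprint counts and gene-level RNA-seq
counts for a 2×2 design (footprint/RNA × wild-type/mutant, ≥2 replicates
each), `ribote`:

- counts footprints per CDS while **excluding the first 15 and last 5
  codons** (elongation-inhibitor edge artifacts) and counts annotated
  uORFs full-length;
- filters genes with **fewer than 128 total mRNA reads** across the four
  libraries of a strain pair;
- normalizes libraries with **median-of-ratios size factors** (per
  assay) and tests each gene's mutant-vs-WT change in relative TE with a
  **negative-binomial interaction Wald test** (trend-shrunken
  method-of-moments dispersions, Benjamini–Hochberg adjustment), then
  classifies significant genes by fold change (≥50% / ≥100%, up / down);
- scores 5′-UTR features: transcript-leader (TL) length via a
  **dominant-isoform rule** (top isoform ≥40% of transcripts and ≥2× the
  runner-up), per-nt structure (PARS) statistics over the whole TL and
  the First30 / Start30 / Plus30 / Max30 windows, start-codon context
  (−6..+4 log-odds PWM), sequence-logo matrices, uORF cap distances and
  closed-loop group labels;
- runs the association layer: Spearman/Pearson correlations,
  hypergeometric set overlaps, Wilcoxon and ANOVA+Tukey group contrasts,
  Ward hierarchical clustering, and comparisons against external
  delta-TE tables.

The `simulate` module generates the whole input bundle (GFF3 annotation,
FASTA sequences, bedGraph PARS tracks, isoform tables, NB-distributed
counts with planted size factors and planted feature-linked TE effects)
with a recorded truth table, so every rule and statistic is testable
against known ground truth at desk scale.

## Command line

```sh
# simulate a dataset with ground truth
ribote simulate --seed 1 --n-genes 500 --outdir sim/

# count CDS/uORF footprints and apply the 128-read mRNA filter
ribote quantify --annotation sim/annotation.gff3 \
    --positions sim/rp_positions.tsv --rna sim/rna_counts.tsv \
    --samples sim/samples.tsv --out counts/

# per-gene delta-TE test
ribote diffte --counts counts/ --out te_results.tsv

# per-gene feature table
ribote features --annotation sim/annotation.gff3 --fasta sim/transcripts.fa \
    --pars sim/pars.bedgraph --isoforms sim/isoforms.tsv --out features.tsv

# association statistics (optionally vs an external delta-TE table)
ribote assoc --te te_results.tsv --features features.tsv --out report.tsv

# or everything from one YAML config
ribote run --config run.yaml
```

A minimal `run.yaml`:

```yaml
outdir: out/
sim:
  n_genes: 500
  seed: 1
  frac_null: 0.5
  effect_model:
    utr_length: -0.003
    noise_sd: 0.2
```

Exit codes: 0 ok, 1 input error, 2 internal/usage error.

## Conventions

- Internal coordinates are 0-based half-open in the transcript frame;
  GFF3 I/O converts to/from that format's 1-based inclusive convention,
  bedGraph is 0-based half-open.
- NB parameterization: `variance = mean + dispersion * mean**2`.
- Missing PARS values make any window statistic that touches them
  missing; TLs shorter than 30 nt have no First30/Max30 value.
- uORF delta-TE reuses the host gene's RNA counts as denominator; uORFs
  inherit the host gene's expression-filter status.
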