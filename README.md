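# hmcmap

Analysis toolkit for genome-wide 5-hydroxymethylcytosine (5hmC) maps across
human tissue panels: tissue-specificity classification of 5hmC-modified and
expressed genes, rank-concordance statistics between 5hmC and expression,
and interval-based enrichment of 5hmC peaks over genomic features and
chromatin states — plus a synthetic-data generator with planted ground truth
so every stage is testable at desk scale.

It is aimed at epigenomics researchers working with 5hmC-Seal (or similar
pull-down) profiles alongside RNA-seq from multi-tissue, multi-donor designs.

## What it computes

**Tiered tissue specificity.** From a gene × sample RPKM-like matrix,
donor samples are averaged per tissue and each gene receives one category,
in decreasing stringency (fold cutoff *F*, abundance cutoff *A*):

- *tissue enriched* in tissue *t*: v_t ≥ F · max_{s≠t} v_s and v_t ≥ A;
- *group enriched* in group *G* (|G| in a configured range, e.g. 2–7):
  mean_{t∈G} v_t ≥ F · max_{s∉G} v_s and the group mean ≥ A;
- *tissue enhanced* in *t*: v_t ≥ F · mean_{s≠t} v_s and v_t ≥ A;
- otherwise *not specific*, or *low signal* if max_t v_t < A.

The conventional settings are F = 2, A = 10 (RPKM) for gene-body 5hmC and
F = 4, A = 1 for expression. By default only *tissue enriched* and *tissue
enhanced* genes count as tissue-specific.

**Rank concordance.** Correspondence-at-the-top (CAT) curves —
overlap(f) = |top_k(a) ∩ top_k(b)|/k with k = ⌈f·n⌉ — between 5hmC and
expression rankings (identical rankings sit at 1; independent rankings have
expectation f); top-fraction coverage of a reference set (e.g. transcription
factors) and its signed difference between two rankings; Pearson/Spearman
gene-level correlation and Spearman correlation of two coverage tracks over
200-kb genomic windows.

**Interval enrichment.** Genome partition into promoter (−1 kb to +100 bp of
the TSS, strand-oriented) / exon / intron / intergenic; fold enrichment of
peak base pairs per label against genome composition, for that partition or
any labelled segmentation (e.g. 15-state chromHMM); empirical nulls from
length-preserving uniform peak shuffles; and gene-set overlap enrichment
fold = (|A∩B|/|A|)/(|B|/|U|) with hypergeometric p, including the tissue ×
tissue cross-enrichment matrix of 5hmC-specific vs expression-specific sets.

**Metagene profiles.** Scaled TSS→TES profiles from binned coverage tracks
(fixed-width flanks, body rescaled to a fixed bin count, minus-strand genes
reversed) with RPKM track normalisation.

## Worked example

```python
from hmcmap import (SimulationConfig, simulate_signal_matrix,
                    TissueSpecificityModel, SpecificityParams)

cfg = SimulationConfig(n_genes=500, n_enriched=30, n_enhanced=10, n_group=10, seed=7)
matrix, samples, truth = simulate_signal_matrix(cfg)   # 19 tissues x 5 donors
res = TissueSpecificityModel(matrix, samples, SpecificityParams.for_hmc()).fit()
print(res.summary())
```

```
Tissue specificity classification
=================================
genes: 500   tissues: 19
fold_cutoff: 2.0   abundance_cutoff: 10.0   group sizes: 2-7

category counts:
  tissue_enriched      30
  group_enriched       10
  tissue_enhanced      10
  not_specific        422
  low_signal           28
...
```

The simulation planted 30 enriched, 10 enhanced and 10 group-enriched genes,
and the classifier recovers exactly those counts; the remaining genes are
flat baselines, 28 of which sit below the 10-RPKM abundance cutoff
(*low signal*). Per-gene calls carry the target tissue(s) and the achieved
fold ratio:

```
gene_id        category target_tissues  fold_score
 g00000 tissue_enriched          liver    3.655905
 g00001 tissue_enriched        stomach    3.745778
 g00002 tissue_enriched          heart    3.634849
```

The same stages are available from the shell:

```bash
hmcmap simulate --seed 7 --out-dir sim/
hmcmap classify --matrix sim/hmc_matrix.tsv --samples sim/samples.tsv --out-dir calls/
hmcmap enrich --peaks sim/peaks.bed --segmentation sim/features.bed \
       --genome sim/genome.tsv --shuffles 200 --seed 1 --out-dir enr/
hmcmap metagene --track sim/coverage.bedgraph --genes sim/genes.bed12 \
       --genome sim/genome.tsv --out-dir mg/
```

Every run writes TSV outputs plus a JSON manifest (parameters, input
digests, seed, version); deterministic subcommands are bit-reproducible.

## Documentation

`docs/methods.md` describes the model and procedure assumptions, the
synthetic-data generator's design (including what it does and does not
emulate about real 5hmC data), numerical choices, and known limitations.
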