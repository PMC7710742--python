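# Methods

## Scope and data model

The package operates downstream of read processing: its inputs are gene ×
sample abundance matrices (RPKM-like, non-negative), called peak intervals
(BED), gene models (BED12 or minimal GTF), labelled genome segmentations
(BED4), and binned coverage tracks (bedGraph). All coordinates are held
0-based half-open; GTF's 1-based closed records are converted at the I/O
boundary and converted back on write. Gene models collapse transcripts
sharing a `gene_id` to the union of their exons, since every analysis here
is gene-level.

## Tiered specificity classification

Each gene's per-tissue value is the arithmetic mean of its donor samples
(median optional). Classification applies three rules in decreasing
stringency — tissue enriched, group enriched, tissue enhanced — with a fold
cutoff *F* > 1 and an abundance cutoff *A* applied to the candidate value or
group mean (not to the other tissues). Fold comparisons use ≥ ("at least
*F*-fold"). A gene whose maximum value is below *A* is *low signal*;
otherwise, if no rule fires, *not specific*. Each gene receives exactly one
category.

Decisions the rule statement leaves open, fixed here:

- **Precedence.** enriched → group enriched → enhanced, mirroring the
  stringency ordering of the Human Protein Atlas scheme this classification
  follows. Evaluation order matters: an enhanced-qualifying gene that also
  qualifies as enriched is reported enriched.
- **Group search.** For each allowed group size *k*, only the top-*k*
  tissues by value need testing: the top-*k* set maximises the group mean
  and minimises the maximum outside, so it qualifies whenever any size-*k*
  group does. Qualifying groups prefer the smallest size, then the highest
  mean, then lexicographic tissue order (ties in values are broken
  lexicographically before taking the top *k*). The test suite verifies
  this shortcut against exhaustive enumeration of all groups.
- **Ties in the enhanced rule.** Several tissues can satisfy it
  simultaneously; the highest-value tissue (then lexicographic) is
  reported.
- **Zero denominators.** If all other tissues are exactly 0 and the
  candidate passes the abundance cutoff, the rule fires with fold score
  +inf. No pseudocount is added.
- **Rules require a positive candidate**, so an all-zero gene with A = 0 is
  *not specific* rather than enriched-with-undefined-fold.
- **Scale behaviour.** Fold comparisons are scale-free: with A = 0 the call
  is invariant to multiplying all values by c > 0. With A > 0, scaling up
  can release abundance-gated rules and thereby move a gene to a
  higher-precedence category (and can only move genes out of *low signal*);
  the per-rule fold ratios themselves never change.

Default parameters: F = 2, A = 10, groups 2–7 for 5hmC gene-body signal
(`SpecificityParams.for_hmc()`); F = 4, A = 1 for RNA
(`SpecificityParams.for_rna()`, group maximum 5 following the HPA
convention, configurable up to the 5hmC-style 7). Only *tissue enriched*
and *tissue enhanced* count as tissue-specific by default.

Row z-scores for heatmap display use the population standard deviation
(ddof = 0), so a two-tissue row {0, 10} maps to {−1, +1}; constant rows
return all-zero z-scores with a warning.

## Rank concordance

CAT curves use k = ⌈f·n⌉ (rounding convention chosen here; the statistic is
insensitive at the plotted 1%-grid). Rankings built from scores break ties
by descending score, then stable input order. Coverage subtraction is the
exact count difference and is antisymmetric by construction. The
windowed-track correlation tiles the genome with non-overlapping windows
(default 200 kb) of per-window mean signal and drops windows with zero
coverage in both tracks before computing Spearman's ρ — retaining such
windows would inflate the correlation through tied zeros.

## Interval enrichment

The functional partition paints promoter (strand-oriented −1000/+100 bp of
the TSS, truncated at chromosome ends) over exon over intron onto the
genome; everything unpainted is intergenic, and the partition covers each
chromosome exactly once. Enrichment's `bp` mode compares the fraction of
peak base pairs per label with the label's fraction of segmentation base
pairs, so observed and expected fractions each sum to 1 and a whole-genome
"peak" has fold 1 for every label; `peak_majority` mode assigns each peak
its maximal-overlap label (vocabulary order breaks ties) for count-based
summaries. Labels absent from the genome yield fold NaN, flagged rather
than zero.

Shuffle nulls reposition each interval uniformly on its source chromosome
(preserving length, count and chromosome composition; an any-chromosome
option weights hosts by feasible placements), rejecting placements that
intersect an optional exclusion set with bounded retries. The
`SegmentationEnrichment.fit(shuffles=N)` results report per-label null
mean, null sd, and the add-one empirical upper-tail p.

Set enrichment uses fold = (|A∩B|/|A|)/(|B|/|U|) — symmetric in A and B —
with the upper-tail hypergeometric p. The tissue × tissue cross-matrix
takes an explicit gene universe (the appropriate universe is
analysis-dependent and is deliberately not defaulted); tissues lacking
specific genes on either side yield NaN entries.

## Metagene profiles

Scale-regions semantics: fixed-width flank bins at the track's bin size,
gene body split into `body_bins` equal sub-intervals whose values are
length-weighted means of overlapping track bins (genes shorter than
`body_bins` track bins are thereby upsampled by fractional overlap), and
minus-strand genes reversed so profiles run TSS→TES. The cross-gene mean is
unweighted; flank bins beyond a chromosome end are NaN for that gene and
excluded from the mean. Defaults (3 kb flanks, 100 body bins) are
conventional plotting choices, not estimates. RPKM track normalisation is
count / ((bin_size/1000) · (reads/10⁶)).

## Synthetic data generator

The generator emulates the structure of a multi-tissue 5hmC/RNA study — 19
tissues, 5 donors per tissue, log-normal baseline abundance (median 30,
σ_log = 0.8, RPKM-like scale), multiplicative log-normal donor noise with a
10% coefficient of variation, and planted specificity at fold 4 against the
F = 2 / A = 10 classifier (a twofold margin over the rule threshold) —
plus toy genomes, class-weighted peak sets and dip-shaped coverage tracks.
Noise is mean-preserving (log-normal with E = 1), so CV = 0 recovery is
exact by construction. Planted baselines are floored at 12 so planted
signal is never abundance-censored.

Planting an *enhanced-but-not-enriched-and-not-group* gene is the delicate
case: with homogeneous other tissues the enhanced and enriched rules
coincide, while a single high decoy tissue triggers the group rule. The
generator therefore raises `n_decoys` = 7 decoy tissues (one more than the
largest group that could otherwise swallow them at the default group range)
to a level *d* solved so the target's fold over the mean of others equals
the requested planted fold while its fold over *d* is a fixed ratio of 1.7,
safely below the enriched cutoff of 2; every candidate group then leaves a
decoy outside and fails its fold test with margin. The ratio 1.7 balances
the distance to the enriched rule (ratio 2) against decoy levels growing
unboundedly as the ratio approaches the feasibility limit.

What the simulation does *not* emulate about real data: gene-length and
GC-dependent coverage biases, correlated donor effects (donor noise is
i.i.d. across genes), peak-calling artefacts, chromosomal domain structure,
and the empirical dependence between 5hmC and expression levels. Passing
tests therefore demonstrate the correctness and calibration of the
*algorithms* under their stated models, not biological performance on real
5hmC-Seal libraries.

All randomness descends from a single seed through named child generators
(`SeedSequence([seed, crc32(name)])`), so adding one sub-simulation never
perturbs another's draws, and every stage is bit-reproducible under a fixed
seed.

## Problem sizes and numerical choices

The calibration script and acceptance-style tests use a 2,000-gene ×
19-tissue × 5-donor matrix for recovery, 1,000 random 8-tissue vectors for
oracle agreement, 500 random ranking pairs of 1,000 items for CAT
calibration, a 2 × 1 Mb toy genome with 60 genes for enrichment (200
shuffles of 1,000 peaks; 10,000 short peaks for the closed-form check, kept
short so boundary spillover is negligible against the Monte-Carlo error),
and 5,000 null draws with a wide-support design (|U| = 2 × 10⁶) for p-value
uniformity, where the discreteness of the hypergeometric distribution is
fine enough not to distort the comparison with the uniform.

Monte-Carlo checks use 3–4 standard-error bands. Exactness checks
(metagene shapes, unit folds, round-trips) are asserted at 1e-9 or exact
equality; one bedGraph re-binning step may cost one ulp on a truncated
final bin.

## Known limitations

- `classify_gene` is a per-gene Python loop; at 10⁵+ genes a vectorised
  path would be preferable.
- The genome painter materialises per-base arrays; practical for
  chromosomes up to ~10⁸ bp but not optimal for full mammalian genomes with
  many labels (the enrichment accounting itself is interval-based and
  scales well).
- bigWig input is not supported; tracks are read from bedGraph.
- The "sliding" window correlation uses non-overlapping tiles; an
  overlapping-step option would add little information but is not
  implemented.
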