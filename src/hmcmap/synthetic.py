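"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the structure of a multi-tissue 5hmC/expression study:
per-tissue donor replicate matrices with planted tissue-enriched, enhanced and
group-enriched genes under multiplicative log-normal noise; a toy genome with
non-overlapping stranded gene models; peak sets with controllable per-feature-
class placement density; and coverage tracks with gene-body elevation and a
localized TSS dip.

Planting notes
--------------
* ``tissue_enriched`` genes multiply one tissue's mean by ``planted_fold``.
* ``group_enriched`` genes multiply a small tissue group by ``planted_fold``;
  no strict subgroup qualifies, so the classifier recovers the exact group.
* ``tissue_enhanced`` genes need decoy structure: with homogeneous other
  tissues the enhanced rule coincides with the (higher-precedence) enriched
  rule, and a single high decoy triggers the group rule instead. The generator
  therefore plants ``n_decoys`` decoy tissues at a level *d* solved so that the
  target's fold over the mean of the others is exactly ``planted_fold`` while
  its fold over the decoy level is a fixed sub-threshold ratio
  (``decoy_enriched_ratio`` < classifier fold cutoff). Any candidate group of
  allowed size leaves at least one decoy outside, keeping the group rule quiet.

All randomness flows from ``seed`` through a named child generator per
sub-simulation, so adding one simulation does not perturb another's draws.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import build_feature_segmentation
from .io import (
    CoverageTrack,
    GeneModel,
    GenomeTable,
    IntervalSet,
    SampleTable,
    Segmentation,
    SignalMatrix,
)

__all__ = [
    "DEFAULT_TISSUES",
    "SimulationConfig",
    "simulate_signal_matrix",
    "simulate_genome",
    "simulate_peaks",
    "simulate_coverage",
]

# 19 tissue types across ten organ systems, mirroring a broad human tissue panel
DEFAULT_TISSUES = (
    "brain", "hypothalamus", "heart", "artery", "sigmoid_colon", "transverse_colon",
    "stomach", "liver", "pancreas", "small_intestine", "lung", "kidney", "bladder",
    "ovary", "testis", "placenta", "skin", "bone_marrow", "lymph_node",
)


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic named child generator derived from one root seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the signal-matrix simulation.

    Defaults mirror the emulated study design: 19 tissues with 5 donors each,
    planted specificity folds of 4 against classifier cutoffs of fold 2 /
    abundance 10, log-normal RPKM-like baselines (median ≈ 30) and 10%
    multiplicative donor noise.
    """

    n_genes: int = 2000
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    donors_per_tissue: int = 5
    n_enriched: int = 100
    n_enhanced: int = 60
    n_group: int = 40
    group_size_range: tuple[int, int] = (2, 3)
    planted_fold: float = 4.0
    baseline_median: float = 30.0
    baseline_sigma: float = 0.8
    noise_cv: float = 0.1
    abundance_cutoff: float = 10.0
    min_planted_baseline: float = 12.0
    n_decoys: int = 7
    decoy_enriched_ratio: float = 1.7
    seed: int = 0

    def __post_init__(self):
        if self.planted_fold <= 1:
            raise ValueError("planted_fold must exceed 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        n_planted = self.n_enriched + self.n_enhanced + self.n_group
        if n_planted > self.n_genes:
            raise ValueError("more planted genes than genes")
        if self.group_size_range[0] < 2 or self.group_size_range[1] < self.group_size_range[0]:
            raise ValueError("invalid group_size_range")
        if self.group_size_range[1] >= len(self.tissues):
            raise ValueError("planted group size must be below the number of tissues")
        if self.n_decoys + 2 > len(self.tissues):
            raise ValueError("n_decoys leaves no baseline tissue")


def _enhanced_levels(cfg: SimulationConfig, baseline: float) -> tuple[float, float]:
    """Solve decoy level d and target level v for an enhanced-only planting."""
    T = len(cfg.tissues)
    m, D = T - 1, cfg.n_decoys
    R = m - D
    denom = cfg.decoy_enriched_ratio * m - cfg.planted_fold * D
    if denom <= 0 or R <= 0:
        raise ValueError(
            "enhanced planting infeasible: need decoy_enriched_ratio * (T-1) > planted_fold * n_decoys"
        )
    d = cfg.planted_fold * R * baseline / denom
    return d, cfg.decoy_enriched_ratio * d


def simulate_signal_matrix(
    cfg: SimulationConfig,
) -> tuple[SignalMatrix, SampleTable, pd.DataFrame]:
    """Simulate a gene × sample matrix with planted specificity structure.

    Returns the matrix, the sample table, and the truth table (gene_id,
    category, target_tissues comma-joined, true_fold). Unplanted genes are
    labelled ``not_specific`` or ``low_signal`` according to whether their
    baseline reaches ``cfg.abundance_cutoff``.
    """
    rng = child_rng(cfg.seed, "signal_matrix")
    T = len(cfg.tissues)
    mu = math.log(cfg.baseline_median)
    baselines = np.exp(rng.normal(mu, cfg.baseline_sigma, size=cfg.n_genes))

    n_planted = cfg.n_enriched + cfg.n_enhanced + cfg.n_group
    baselines[:n_planted] = np.maximum(baselines[:n_planted], cfg.min_planted_baseline)

    tissue_means = np.tile(baselines[:, None], (1, T))
    truth_rows = []
    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
    gi = 0
    for _ in range(cfg.n_enriched):
        t = int(rng.integers(T))
        tissue_means[gi, t] = baselines[gi] * cfg.planted_fold
        truth_rows.append((gene_ids[gi], "tissue_enriched", (cfg.tissues[t],), cfg.planted_fold))
        gi += 1
    for _ in range(cfg.n_enhanced):
        d, v = _enhanced_levels(cfg, baselines[gi])
        others = rng.permutation(T)
        target, decoys = int(others[0]), others[1 : 1 + cfg.n_decoys]
        tissue_means[gi, decoys] = d
        tissue_means[gi, target] = v
        truth_rows.append((gene_ids[gi], "tissue_enhanced", (cfg.tissues[target],), cfg.planted_fold))
        gi += 1
    for _ in range(cfg.n_group):
        g = int(rng.integers(cfg.group_size_range[0], cfg.group_size_range[1] + 1))
        members = rng.permutation(T)[:g]
        tissue_means[gi, members] = baselines[gi] * cfg.planted_fold
        labels = tuple(sorted(cfg.tissues[t] for t in members))
        truth_rows.append((gene_ids[gi], "group_enriched", labels, cfg.planted_fold))
        gi += 1
    for i in range(gi, cfg.n_genes):
        cat = "not_specific" if baselines[i] >= cfg.abundance_cutoff else "low_signal"
        truth_rows.append((gene_ids[i], cat, (), 1.0))

    samples, tissue_col, donor_col = [], [], []
    for t in cfg.tissues:
        for d_i in range(cfg.donors_per_tissue):
            samples.append(f"{t}_d{d_i + 1}")
            tissue_col.append(t)
            donor_col.append(f"d{d_i + 1}")
    table = SampleTable(
        pd.DataFrame({"sample_id": samples, "tissue": tissue_col, "donor": donor_col})
    )

    n_samples = T * cfg.donors_per_tissue
    values = np.repeat(tissue_means, cfg.donors_per_tissue, axis=1)
    if cfg.noise_cv > 0:
        sigma = math.sqrt(math.log(1 + cfg.noise_cv**2))
        noise = np.exp(rng.normal(-sigma**2 / 2, sigma, size=(cfg.n_genes, n_samples)))
        values = values * noise
    matrix = SignalMatrix(pd.DataFrame(values, index=gene_ids, columns=samples))
    truth = pd.DataFrame(
        {
            "gene_id": [r[0] for r in truth_rows],
            "category": [r[1] for r in truth_rows],
            "target_tissues": [",".join(r[2]) for r in truth_rows],
            "true_fold": [r[3] for r in truth_rows],
        }
    )
    return matrix, table, truth


def simulate_genome(
    n_chroms: int = 2,
    chrom_length: int = 1_000_000,
    n_genes: int = 50,
    gene_length_range: tuple[int, int] = (5_000, 20_000),
    exons_per_gene: int = 3,
    seed: int = 0,
    align_to: int = 1,
    margin: int = 5_000,
) -> tuple[GenomeTable, list[GeneModel], Segmentation]:
    """A toy genome: non-overlapping stranded genes plus its feature partition.

    ``align_to`` snaps gene boundaries to multiples of that many bp (useful to
    make metagene binning exact); ``margin`` keeps genes plus promoter flanks
    inside chromosome bounds.
    """
    rng = child_rng(seed, "genome")
    genome = GenomeTable({f"chr{i + 1}": chrom_length for i in range(n_chroms)})
    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0) for i in range(n_chroms)]
    max_len = gene_length_range[1]
    genes: list[GeneModel] = []
    idx = 0
    for ci, count in enumerate(per_chrom):
        usable = chrom_length - 2 * margin
        if count * (max_len + align_to) + count * 1000 > usable:
            raise ValueError("infeasible gene density for chromosome length")
        slot = usable // max(count, 1)
        for k in range(count):
            length = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
            length = max(align_to, (length // align_to) * align_to)
            lo = margin + k * slot
            hi = min(margin + (k + 1) * slot, chrom_length - margin) - length
            start = int(rng.integers(lo, max(hi, lo + 1)))
            start = (start // align_to) * align_to
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _random_exons(rng, start, end, exons_per_gene, align_to)
            genes.append(GeneModel(f"gene{idx:04d}", f"chr{ci + 1}", start, end, strand, exons))
            idx += 1
    seg = build_feature_segmentation(genes, genome)
    return genome, genes, seg


def _random_exons(rng, start, end, n_exons, align_to) -> tuple[tuple[int, int], ...]:
    length = end - start
    n_exons = max(1, min(n_exons, length // (2 * max(align_to, 200))))
    if n_exons == 1:
        return ((start, end),)
    # cut the span into 2*n_exons-1 alternating exon/intron blocks
    cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 2, replace=False))
    bounds = np.concatenate([[0], cuts, [length]])
    exons = []
    for i in range(0, len(bounds) - 1, 2):
        s, e = start + int(bounds[i]), start + int(bounds[i + 1])
        if e > s:
            exons.append((s, e))
    return tuple(exons)


def simulate_peaks(
    seg: Segmentation,
    class_weights: dict[str, float],
    n_peaks: int,
    length_range: tuple[int, int] = (100, 300),
    seed: int = 0,
) -> IntervalSet:
    """Place peaks with per-class density proportional to weight × class bp.

    A peak's anchor base is drawn from a label class chosen with probability
    ∝ weight × class bp, then uniformly within that class; the peak is
    centred on the anchor and clipped at chromosome ends. For peaks short
    relative to segment sizes the expected bp-mode enrichment fold of class c
    is weight_c / Σ_ℓ weight_ℓ · expected_fraction_ℓ.
    """
    rng = child_rng(seed, "peaks")
    weights = np.array([float(class_weights.get(lab, 0.0)) for lab in seg.vocabulary])
    if (weights < 0).any() or weights.sum() == 0:
        raise ValueError("class weights must be non-negative and not all zero")
    label_bp = seg.label_bp().to_numpy(float)
    for lab, w, bp in zip(seg.vocabulary, weights, label_bp):
        if w > 0 and bp == 0:
            raise ValueError(f"class {lab!r} has positive weight but no genome bp")
    class_p = weights * label_bp
    class_p = class_p / class_p.sum()

    # per class: segment arrays and cumulative bp for uniform base sampling
    df = seg.df
    by_class = {}
    code = {lab: i for i, lab in enumerate(seg.vocabulary)}
    for lab in seg.vocabulary:
        sub = df[df["label"] == lab]
        if len(sub):
            lens = (sub["end"] - sub["start"]).to_numpy(np.int64)
            by_class[code[lab]] = (
                sub["chrom"].to_numpy(),
                sub["start"].to_numpy(np.int64),
                np.concatenate([[0], np.cumsum(lens)]),
            )
    rows = []
    classes = rng.choice(len(seg.vocabulary), size=n_peaks, p=class_p)
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=n_peaks)
    for cls, length in zip(classes, lengths):
        chroms, starts, cum = by_class[int(cls)]
        offset = int(rng.integers(0, cum[-1]))
        seg_i = int(np.searchsorted(cum, offset, side="right") - 1)
        anchor = int(starts[seg_i] + (offset - cum[seg_i]))
        chrom = chroms[seg_i]
        half = int(length) // 2
        s = max(0, anchor - half)
        e = min(seg.genome[chrom], s + int(length))
        s = max(0, e - int(length))
        rows.append((chrom, s, e))
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]), seg.genome)


def simulate_coverage(
    genes: list[GeneModel],
    genome: GenomeTable,
    body_level: float = 5.0,
    tss_dip_depth: float = 4.0,
    flank_level: float = 1.0,
    bin_size: int = 100,
    noise_sd: float = 0.0,
    seed: int = 0,
    dip_bp: int | None = None,
) -> CoverageTrack:
    """A coverage track with gene-body elevation and a localized TSS dip.

    Per-base signal: ``flank_level`` background, ``body_level`` over gene
    bodies, and ``body_level − tss_dip_depth`` over the first ``dip_bp``
    bases of each body from the TSS (default: one bin). Bases are averaged
    into bins, then Gaussian noise (sd ``noise_sd``) is added and truncated
    at zero.
    """
    if min(body_level, flank_level) < 0 or tss_dip_depth < 0:
        raise ValueError("levels must be non-negative")
    if tss_dip_depth > body_level:
        raise ValueError("dip depth cannot exceed the body level")
    if genes and bin_size > min(g.length for g in genes):
        raise ValueError("bin_size larger than the smallest gene")
    dip_bp = bin_size if dip_bp is None else dip_bp
    rng = child_rng(seed, "coverage")
    data = {}
    base = {chrom: np.full(length, flank_level) for chrom, length in genome}
    for g in genes:
        arr = base[g.chrom]
        arr[g.start : g.end] = body_level
    for g in genes:
        arr = base[g.chrom]
        if g.strand == "+":
            s, e = g.start, min(g.start + dip_bp, g.end)
        else:
            s, e = max(g.end - dip_bp, g.start), g.end
        arr[s:e] = body_level - tss_dip_depth
    for chrom, length in genome:
        nbins = -(-length // bin_size)
        pad = nbins * bin_size - length
        per_base = base[chrom]
        if pad:
            per_base = np.concatenate([per_base, np.zeros(pad)])
        binned = per_base.reshape(nbins, bin_size).mean(axis=1)
        if pad:  # last bin average over real bases only
            binned[-1] = base[chrom][(nbins - 1) * bin_size :].mean()
        if noise_sd > 0:
            binned = np.clip(binned + rng.normal(0, noise_sd, size=nbins), 0, None)
        data[chrom] = binned
    return CoverageTrack(bin_size, genome, data)
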