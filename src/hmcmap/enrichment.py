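"""Interval- and set-based fold enrichment.

Peak sets (e.g. 5hmC peaks) are compared against a labelled genome
segmentation — either a functional partition (promoter/exon/intron/
intergenic, with promoters defined as −1 kb to +100 bp of the TSS) or an
external chromatin-state segmentation. Observed fractions of peak base
pairs per label are divided by the genome-composition expectation, and an
empirical null is available from length-preserving uniform shuffles of the
peaks. Gene-set overlap enrichment (fold + hypergeometric p) supports
cross-tissue comparison of specificity calls.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneModel, GenomeTable, IntervalSet, Segmentation
from .specificity import SpecificityCall

__all__ = [
    "FEATURE_LABELS",
    "build_feature_segmentation",
    "segmentation_enrichment",
    "shuffle_intervals",
    "overlap_enrichment",
    "set_fold_enrichment",
    "cross_tissue_enrichment_matrix",
    "SegmentationEnrichment",
    "EnrichmentResults",
]

FEATURE_LABELS = ("promoter", "exon", "intron", "intergenic")


def build_feature_segmentation(
    genes: Sequence[GeneModel],
    genome: GenomeTable,
    promoter_upstream: int = 1000,
    promoter_downstream: int = 100,
) -> Segmentation:
    """Partition the genome into promoter/exon/intron/intergenic.

    Promoters span −``promoter_upstream``..+``promoter_downstream`` of the TSS,
    oriented by strand and truncated at chromosome ends. Where classes overlap
    the precedence is promoter > exon > intron; everything else is intergenic.
    The result covers every chromosome exactly once.
    """
    if promoter_upstream < 0 or promoter_downstream < 0:
        raise ValueError("promoter window sizes must be non-negative")
    # paint codes: 0 intergenic < 1 intron < 2 exon < 3 promoter
    code = {"intergenic": 0, "intron": 1, "exon": 2, "promoter": 3}
    paint = {chrom: np.zeros(length, dtype=np.int8) for chrom, length in genome}
    for rank, kind in ((1, "intron"), (2, "exon"), (3, "promoter")):
        for g in genes:
            arr = paint[g.chrom]
            if kind == "intron":
                arr[g.start : g.end] = np.maximum(arr[g.start : g.end], rank)
            elif kind == "exon":
                for s, e in g.exons:
                    arr[s:e] = np.maximum(arr[s:e], rank)
            else:
                if g.strand == "+":
                    s, e = g.tss - promoter_upstream, g.tss + promoter_downstream
                else:
                    s, e = g.tss - promoter_downstream, g.tss + promoter_upstream
                s, e = max(0, s), min(len(arr), e)
                if s < e:
                    arr[s:e] = np.maximum(arr[s:e], rank)
    rows = []
    names = {v: k for k, v in code.items()}
    for chrom, arr in paint.items():
        breaks = np.flatnonzero(np.diff(arr)) + 1
        bounds = np.concatenate([[0], breaks, [len(arr)]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            rows.append((chrom, int(s), int(e), names[int(arr[s])]))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return Segmentation(df, FEATURE_LABELS, genome)


def _peak_label_bp(peaks: IntervalSet, seg: Segmentation) -> np.ndarray:
    """(n_peaks × n_labels) bp overlap matrix via searchsorted on the sorted partition."""
    per_chrom = seg.per_chrom()
    n_labels = len(seg.vocabulary)
    out = np.zeros((len(peaks), n_labels))
    for row_i, (chrom, start, end) in enumerate(
        zip(peaks.df["chrom"], peaks.df["start"], peaks.df["end"])
    ):
        if chrom not in per_chrom:
            continue
        starts, ends, codes = per_chrom[chrom]
        i0 = np.searchsorted(ends, start, side="right")
        i1 = np.searchsorted(starts, end, side="left")
        if i0 >= i1:
            continue
        lo = np.maximum(starts[i0:i1], start)
        hi = np.minimum(ends[i0:i1], end)
        np.add.at(out[row_i], codes[i0:i1], np.maximum(hi - lo, 0))
    return out


@dataclass(frozen=True)
class LabelEnrichment:
    label: str
    observed_fraction: float
    expected_fraction: float
    fold: float  # nan when expected is 0


def segmentation_enrichment(
    peaks: IntervalSet, seg: Segmentation, mode: str = "bp"
) -> pd.DataFrame:
    """Fold enrichment of peaks over segmentation labels.

    ``bp`` mode: observed = peak bp overlapping the label / total peak bp in
    the segmentation; expected = label bp / segmentation bp. ``peak_majority``
    mode: each peak counts once under its maximal-overlap label (vocabulary
    order breaks ties); fractions are over peaks with any overlap.
    Labels absent from the genome get expected 0 and fold NaN.
    """
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    if peaks.genome != seg.genome:
        raise ValueError("peaks and segmentation use different genome tables")
    if mode not in ("bp", "peak_majority"):
        raise ValueError(f"unknown mode {mode!r}")
    overlap = _peak_label_bp(peaks, seg)
    label_bp = seg.label_bp().to_numpy(float)
    expected = label_bp / label_bp.sum()
    if mode == "bp":
        per_label = overlap.sum(axis=0)
        total = per_label.sum()
        if total == 0:
            raise ValueError("peaks do not overlap the segmentation")
        observed = per_label / total
    else:
        covered = overlap.sum(axis=1) > 0
        # argmax returns the first (vocabulary-order) label on ties
        assigned = overlap[covered].argmax(axis=1)
        counts = np.bincount(assigned, minlength=len(seg.vocabulary)).astype(float)
        if counts.sum() == 0:
            raise ValueError("peaks do not overlap the segmentation")
        observed = counts / counts.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(expected > 0, observed / expected, np.nan)
    return pd.DataFrame(
        {
            "label": seg.vocabulary,
            "observed_fraction": observed,
            "expected_fraction": expected,
            "fold": fold,
        }
    )


def annotate_peaks(peaks: IntervalSet, seg: Segmentation) -> pd.DataFrame:
    """Per-peak assigned label (maximal bp overlap, vocabulary order on ties)."""
    overlap = _peak_label_bp(peaks, seg)
    labels = np.array(seg.vocabulary, dtype=object)[overlap.argmax(axis=1)]
    labels[overlap.sum(axis=1) == 0] = "unassigned"
    out = peaks.df.loc[:, ["chrom", "start", "end"]].copy()
    out["label"] = labels
    return out


def _excluded_per_chrom(excluded: IntervalSet | None):
    if excluded is None:
        return {}
    out = {}
    df = excluded.sorted().df
    for chrom, sub in df.groupby("chrom", sort=False):
        merged: list[list[int]] = []
        for s, e in zip(sub["start"], sub["end"]):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([int(s), int(e)])
        out[chrom] = (
            np.array([m[0] for m in merged], np.int64),
            np.array([m[1] for m in merged], np.int64),
        )
    return out


def shuffle_intervals(
    peaks: IntervalSet,
    genome: GenomeTable,
    seed,
    excluded: IntervalSet | None = None,
    max_tries: int = 1000,
    any_chromosome: bool = False,
) -> IntervalSet:
    """Uniformly reposition each interval, preserving its length.

    By default each interval stays on its source chromosome (controls for
    chromosome composition); with ``any_chromosome`` the host is drawn with
    probability proportional to the number of feasible start positions.
    Placements overlapping ``excluded`` are rejected and retried up to
    ``max_tries`` times.
    """
    rng = np.random.default_rng(seed)
    excl = _excluded_per_chrom(excluded)
    chroms = genome.chroms
    rows = []
    for chrom, start, end in zip(peaks.df["chrom"], peaks.df["start"], peaks.df["end"]):
        length = end - start
        if any_chromosome:
            feas = np.array([max(genome[c] - length + 1, 0) for c in chroms], float)
            if feas.sum() == 0:
                raise ValueError(f"interval of length {length} fits no chromosome")
        else:
            if length > genome[chrom]:
                raise ValueError(f"interval of length {length} exceeds {chrom}")
        for _ in range(max_tries):
            host = chrom if not any_chromosome else chroms[rng.choice(len(chroms), p=feas / feas.sum())]
            new_start = int(rng.integers(0, genome[host] - length + 1))
            new_end = new_start + length
            if host in excl:
                es, ee = excl[host]
                j = np.searchsorted(ee, new_start, side="right")
                if j < len(es) and es[j] < new_end:
                    continue
            rows.append((host, new_start, new_end))
            break
        else:
            raise RuntimeError(
                f"could not place interval of length {length} after {max_tries} tries"
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return IntervalSet(df, genome)


def overlap_enrichment(overlap: int, n_universe: int, n_a: int, n_b: int) -> dict[str, float]:
    """Fold and upper-tail hypergeometric p for a set overlap given only counts.

    fold = (overlap/|A|) / (|B|/|U|); p = P(X ≥ overlap) for
    X ~ Hypergeom(|U|, |B|, |A|).
    """
    if n_universe <= 0 or n_a <= 0 or n_b <= 0:
        raise ValueError("universe and both sets must be non-empty")
    if overlap < 0 or overlap > min(n_a, n_b):
        raise ValueError("overlap outside feasible range")
    fold = (overlap / n_a) / (n_b / n_universe)
    p = float(stats.hypergeom.sf(overlap - 1, n_universe, n_b, n_a))
    return {
        "overlap": overlap,
        "fold": fold,
        "p_value": p,
        "n_a": n_a,
        "n_b": n_b,
        "n_universe": n_universe,
    }


def set_fold_enrichment(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> dict[str, float]:
    """Overlap fold enrichment of two gene sets within a universe.

    fold = (|A∩B|/|A|) / (|B|/|U|); p is the upper-tail hypergeometric
    probability of at least the observed overlap.
    """
    U, A, B = set(universe), set(set_a), set(set_b)
    if not U or not A or not B:
        raise ValueError("universe and both sets must be non-empty")
    if not A <= U or not B <= U:
        raise ValueError("sets must be subsets of the universe")
    return overlap_enrichment(len(A & B), len(U), len(A), len(B))


def cross_tissue_enrichment_matrix(
    calls_a: Sequence[SpecificityCall],
    calls_b: Sequence[SpecificityCall],
    universe: Iterable[str],
    specific_categories: tuple[str, ...] = ("tissue_enriched", "tissue_enhanced"),
) -> pd.DataFrame:
    """Tissue × tissue fold-enrichment of two specificity call sets.

    Entry (t1, t2) is the fold enrichment of t1-specific genes from
    ``calls_a`` (e.g. 5hmC) within t2-specific genes from ``calls_b``
    (e.g. expression). Tissues with no specific genes in either call set
    yield NaN entries.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    outside = ({c.gene_id for c in calls_a} | {c.gene_id for c in calls_b}) - universe
    if outside:
        raise ValueError(f"call genes outside the universe: {sorted(outside)[:10]}")

    def _by_tissue(calls):
        out: dict[str, set[str]] = {}
        for c in calls:
            if c.category in specific_categories:
                for t in c.target_tissues:
                    out.setdefault(t, set()).add(c.gene_id)
        return out

    by_a, by_b = _by_tissue(calls_a), _by_tissue(calls_b)
    tissues = sorted(set(by_a) | set(by_b))
    mat = pd.DataFrame(np.nan, index=tissues, columns=tissues)
    for t1, t2 in itertools.product(tissues, tissues):
        a, b = by_a.get(t1), by_b.get(t2)
        if a and b:
            mat.loc[t1, t2] = set_fold_enrichment(a, b, universe)["fold"]
    return mat


# ---------------------------------------------------------------------------
# Model / Results presentation
# ---------------------------------------------------------------------------


class SegmentationEnrichment:
    """Peak-over-segmentation enrichment with an optional shuffle null.

    ``fit(shuffles=N, seed=...)`` computes the observed folds and, when N > 0,
    an empirical null (mean, sd, upper-tail p) from length-preserving uniform
    shuffles of the peaks.
    """

    def __init__(self, peaks: IntervalSet, seg: Segmentation, mode: str = "bp"):
        self.peaks = peaks
        self.seg = seg
        self.mode = mode

    def fit(self, shuffles: int = 0, seed=0, excluded: IntervalSet | None = None) -> "EnrichmentResults":
        observed = segmentation_enrichment(self.peaks, self.seg, self.mode)
        null_folds = None
        if shuffles > 0:
            rng = np.random.default_rng(seed)
            draws = []
            for _ in range(shuffles):
                shuf = shuffle_intervals(self.peaks, self.seg.genome, rng, excluded=excluded)
                draws.append(
                    segmentation_enrichment(shuf, self.seg, self.mode)["fold"].to_numpy()
                )
            null_folds = np.vstack(draws)
        return EnrichmentResults(self, observed, null_folds)


class EnrichmentResults:
    """Observed folds per label plus shuffle-null summaries."""

    def __init__(self, model, observed: pd.DataFrame, null_folds: np.ndarray | None):
        self.model = model
        self.observed = observed
        self.null_folds = null_folds

    def to_frame(self) -> pd.DataFrame:
        df = self.observed.copy()
        if self.null_folds is not None:
            n = self.null_folds.shape[0]
            with warnings.catch_warnings():
                # labels absent from the genome are all-NaN across shuffles
                warnings.simplefilter("ignore", RuntimeWarning)
                df["null_mean"] = np.nanmean(self.null_folds, axis=0)
                df["null_sd"] = np.nanstd(self.null_folds, axis=0, ddof=1)
            obs = df["fold"].to_numpy()
            exceed = np.nansum(self.null_folds >= obs[None, :], axis=0)
            df["empirical_p"] = (exceed + 1) / (n + 1)
        return df

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Segmentation enrichment",
            "=======================",
            f"peaks: {len(self.model.peaks)}   mode: {self.model.mode}   "
            f"shuffles: {0 if self.null_folds is None else self.null_folds.shape[0]}",
            "",
            df.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)
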