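"""Rank-concordance statistics between two gene (or enhancer) rankings.

The central object is the correspondence-at-the-top (CAT) curve: for each top
fraction f, the proportion of items shared by the top ⌈f·n⌉ of two rankings of
the same item universe. Identical rankings sit at 1 everywhere; two
independent random rankings have expectation f (the diagonal).

Also provided: coverage of a reference set by the top fraction of a ranking
and the signed difference of such coverages between two rankings (the
"subtraction" statistic used to compare, e.g., the top 10% 5hmC-modified
genes with the top 10% expressed genes against a transcription-factor
catalogue), plus Pearson/Spearman utilities for gene-level and
windowed-track correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CoverageTrack

__all__ = [
    "Ranking",
    "CATCurve",
    "ranking_from_scores",
    "cat_curve",
    "top_fraction_coverage",
    "coverage_subtraction",
    "gene_correlations",
    "windowed_track_correlation",
]


class Ranking:
    """An ordered list of unique item ids, best first."""

    def __init__(self, items: Sequence[str], source: str = ""):
        items = list(items)
        if len(set(items)) != len(items):
            seen, dups = set(), []
            for x in items:
                if x in seen:
                    dups.append(x)
                seen.add(x)
            raise ValueError(f"duplicate items in ranking: {sorted(set(dups))}")
        if not items:
            raise ValueError("empty ranking")
        self.items = items
        self.source = source

    def __len__(self) -> int:
        return len(self.items)

    def top(self, k: int) -> list[str]:
        return self.items[:k]


def ranking_from_scores(scores: pd.Series, source: str = "") -> Ranking:
    """Rank items by descending score; ties broken by stable input order."""
    order = np.argsort(-scores.to_numpy(float), kind="stable")
    return Ranking([str(scores.index[i]) for i in order], source)


@dataclass(frozen=True)
class CATCurve:
    fractions: tuple[float, ...]
    overlap: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fraction": self.fractions, "overlap": self.overlap})


DEFAULT_FRACTIONS = tuple(np.round(np.arange(1, 101) / 100, 2))


def _check_universe(a: Ranking, b: Ranking) -> int:
    ua, ub = set(a.items), set(b.items)
    if ua != ub:
        only_a, only_b = sorted(ua - ub), sorted(ub - ua)
        raise ValueError(
            f"rankings cover different universes: only in a {only_a[:10]}, "
            f"only in b {only_b[:10]}"
        )
    return len(ua)


def cat_curve(
    a: Ranking, b: Ranking, fractions: Iterable[float] = DEFAULT_FRACTIONS
) -> CATCurve:
    """Correspondence at the top: overlap(f) = |top_k(a) ∩ top_k(b)| / k, k = ⌈f·n⌉."""
    n = _check_universe(a, b)
    if n < 2:
        raise ValueError("universe must have at least 2 items")
    fractions = tuple(float(f) for f in fractions)
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError(f"fraction {f} outside (0, 1]")
    overlaps = []
    for f in fractions:
        k = math.ceil(f * n)
        top_a = set(a.items[:k])
        shared = sum(1 for item in b.items[:k] if item in top_a)
        overlaps.append(shared / k)
    return CATCurve(fractions, tuple(overlaps))


def top_fraction_coverage(r: Ranking, refset: Iterable[str], f: float) -> tuple[int, float]:
    """Count (and fraction) of reference-set members inside the top ⌈f·n⌉ of r."""
    refset = set(refset)
    if not refset:
        raise ValueError("empty reference set")
    extra = refset - set(r.items)
    if extra:
        raise ValueError(f"reference items outside the ranking universe: {sorted(extra)[:10]}")
    if not 0 < f <= 1:
        raise ValueError(f"fraction {f} outside (0, 1]")
    k = math.ceil(f * len(r))
    count = sum(1 for item in r.items[:k] if item in refset)
    return count, count / len(refset)


def coverage_subtraction(
    a: Ranking, b: Ranking, refset: Iterable[str], f: float
) -> dict[str, float]:
    """Signed coverage difference count_a − count_b for a shared reference set."""
    _check_universe(a, b)
    refset = set(refset)
    count_a, frac_a = top_fraction_coverage(a, refset, f)
    count_b, frac_b = top_fraction_coverage(b, refset, f)
    return {
        "count_a": count_a,
        "count_b": count_b,
        "difference": count_a - count_b,
        "fraction_a": frac_a,
        "fraction_b": frac_b,
        "fraction_difference": frac_a - frac_b,
    }


def gene_correlations(x, y) -> tuple[float, float]:
    """Pearson r and Spearman ρ (average ranks on ties).

    Zero variance in either vector yields (nan, nan) with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance: correlation undefined", UserWarning, stacklevel=2)
        return float("nan"), float("nan")
    r = stats.pearsonr(x, y).statistic
    rho = stats.spearmanr(x, y).statistic
    return float(r), float(rho)


def windowed_track_correlation(
    a: CoverageTrack, b: CoverageTrack, window_bp: int = 200_000
) -> tuple[float, int]:
    """Spearman ρ of per-window mean signal between two tracks.

    Windows tile each chromosome (non-overlapping, width ``window_bp``, last
    window truncated); windows with zero coverage in *both* tracks are
    dropped. Returns (rho, number of windows used).
    """
    if a.genome != b.genome:
        raise ValueError("tracks are on different genomes")
    if a.bin_size != b.bin_size:
        raise ValueError("tracks have different bin sizes")
    if window_bp % a.bin_size != 0:
        raise ValueError("window_bp must be a multiple of the bin size")
    per = window_bp // a.bin_size
    means_a, means_b = [], []
    for chrom, length in a.genome:
        xa, xb = a.data[chrom], b.data[chrom]
        nbins = len(xa)
        widths = np.minimum((np.arange(nbins) + 1) * a.bin_size, length) - (
            np.arange(nbins) * a.bin_size
        )
        for i0 in range(0, nbins, per):
            w = widths[i0 : i0 + per].astype(float)
            means_a.append(float(np.dot(xa[i0 : i0 + per], w) / w.sum()))
            means_b.append(float(np.dot(xb[i0 : i0 + per], w) / w.sum()))
    means_a = np.array(means_a)
    means_b = np.array(means_b)
    keep = (means_a > 0) | (means_b > 0)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 informative windows")
    rho = stats.spearmanr(means_a[keep], means_b[keep]).statistic
    return float(rho), int(keep.sum())
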