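"""Scaled TSS→TES metagene profiles from binned coverage tracks.

Each gene contributes a fixed number of upstream-flank bins, ``body_bins``
gene-body bins obtained by rescaling the body to a common length
(length-weighted averaging of track bins, deeptools "scale-regions"
semantics), and downstream-flank bins. Minus-strand genes are reversed so
every profile runs TSS→TES. The profile is the unweighted mean across genes;
genes whose flanks are truncated at a chromosome end contribute only to the
bins they cover.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CoverageTrack, GeneModel

__all__ = ["MetageneProfile", "rpkm_normalize_track", "scaled_metagene"]


@dataclass(frozen=True)
class MetageneProfile:
    upstream_bins: int
    body_bins: int
    downstream_bins: int
    values: np.ndarray  # mean signal per bin, TSS→TES orientation
    n_genes: int

    @property
    def total_bins(self) -> int:
        return self.upstream_bins + self.body_bins + self.downstream_bins

    def to_frame(self) -> pd.DataFrame:
        zones = (
            ["upstream"] * self.upstream_bins
            + ["body"] * self.body_bins
            + ["downstream"] * self.downstream_bins
        )
        return pd.DataFrame(
            {"bin": np.arange(self.total_bins), "zone": zones, "signal": self.values}
        )


def rpkm_normalize_track(raw: CoverageTrack, total_mapped_reads: float) -> CoverageTrack:
    """RPKM-normalise a per-bin read-count track.

    value = count / ((bin_size/1000) × (total_mapped_reads/1e6)).
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    scale = (raw.bin_size / 1000.0) * (total_mapped_reads / 1e6)
    data = {chrom: arr / scale for chrom, arr in raw.data.items()}
    return CoverageTrack(raw.bin_size, raw.genome, data)


def _interval_bin_means(
    track: CoverageTrack, chrom: str, start: int, end: int, nbins: int
) -> np.ndarray:
    """Split [start, end) into nbins equal sub-intervals; length-weighted mean each.

    Sub-intervals outside the chromosome give NaN (truncated flanks).
    """
    bounds = start + (end - start) * np.arange(nbins + 1) / nbins
    out = np.empty(nbins)
    length = track.genome[chrom]
    for i in range(nbins):
        lo, hi = bounds[i], bounds[i + 1]
        if hi <= 0 or lo >= length:
            out[i] = np.nan
            continue
        lo_c, hi_c = max(lo, 0.0), min(hi, float(length))
        out[i] = _weighted_mean(track, chrom, lo_c, hi_c)
    return out


def _weighted_mean(track: CoverageTrack, chrom: str, lo: float, hi: float) -> float:
    bs = track.bin_size
    arr = track.data[chrom]
    i0 = int(lo // bs)
    i1 = int(-(-hi // bs))
    idx = np.arange(i0, i1)
    w = np.minimum((idx + 1) * bs, hi) - np.maximum(idx * bs, lo)
    w = np.clip(w, 0, None)
    if w.sum() == 0:
        return np.nan
    return float(np.dot(arr[i0:i1], w) / w.sum())


def scaled_metagene(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    upstream_bp: int = 3000,
    downstream_bp: int = 3000,
    body_bins: int = 100,
    return_matrix: bool = False,
):
    """Mean scaled TSS→TES profile across genes.

    Flanks are sampled in fixed-width bins of the track's bin size (so
    ``upstream_bp``/``downstream_bp`` must be multiples of it); the body is
    rescaled to ``body_bins`` bins. With ``return_matrix`` the per-gene
    (genes × bins) matrix is returned alongside the profile.
    """
    if not genes:
        raise ValueError("empty gene list")
    bs = track.bin_size
    if upstream_bp % bs or downstream_bp % bs:
        raise ValueError("flank widths must be multiples of the track bin size")
    up_bins = upstream_bp // bs
    down_bins = downstream_bp // bs
    total = up_bins + body_bins + down_bins
    rows = np.empty((len(genes), total))
    for gi, g in enumerate(genes):
        if g.length < bs:
            raise ValueError(f"gene {g.gene_id!r} shorter than one track bin")
        # genomic left→right: [start-up, start) flank, body, [end, end+down) flank
        if g.strand == "+":
            left = _interval_bin_means(track, g.chrom, g.start - upstream_bp, g.start, up_bins) if up_bins else np.empty(0)
            body = _interval_bin_means(track, g.chrom, g.start, g.end, body_bins)
            right = _interval_bin_means(track, g.chrom, g.end, g.end + downstream_bp, down_bins) if down_bins else np.empty(0)
            rows[gi] = np.concatenate([left, body, right])
        else:
            # TSS at g.end; build left→right with swapped flank widths, then reverse
            left = _interval_bin_means(track, g.chrom, g.start - downstream_bp, g.start, down_bins) if down_bins else np.empty(0)
            body = _interval_bin_means(track, g.chrom, g.start, g.end, body_bins)
            right = _interval_bin_means(track, g.chrom, g.end, g.end + upstream_bp, up_bins) if up_bins else np.empty(0)
            rows[gi] = np.concatenate([left, body, right])[::-1]
    with warnings.catch_warnings():
        # bins outside every gene's chromosome are all-NaN and stay NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        profile = np.nanmean(rows, axis=0)
    result = MetageneProfile(up_bins, body_bins, down_bins, profile, len(genes))
    if return_matrix:
        return result, pd.DataFrame(rows, index=[g.gene_id for g in genes])
    return result
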