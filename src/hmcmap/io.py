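"""Domain containers and readers/writers for the genomic formats the pipeline touches.

All coordinates are stored 0-based, half-open (BED convention). GTF input
(1-based, closed) is converted at the boundary and converted back on write.

Containers are thin validated wrappers around :class:`pandas.DataFrame` /
:class:`numpy.ndarray`; they exist to make invariants (non-negative signal,
unique ids, sorted non-overlapping segments) explicit at construction time
rather than at first use deep inside an analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeTable",
    "SampleTable",
    "SignalMatrix",
    "GeneModel",
    "IntervalSet",
    "Segmentation",
    "CoverageTrack",
    "read_genome_table",
    "write_genome_table",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_sample_table",
    "write_sample_table",
    "read_bed",
    "write_bed",
    "read_segmentation",
    "write_segmentation",
    "read_gene_models",
    "write_bed12",
    "write_gtf",
    "read_bedgraph",
    "write_bedgraph",
]


class GenomeTable:
    """Ordered chromosome → length table (lengths in bp, > 0)."""

    def __init__(self, lengths: Mapping[str, int]):
        if not lengths:
            raise ValueError("genome table is empty")
        self._lengths: dict[str, int] = {}
        for chrom, length in lengths.items():
            length = int(length)
            if not chrom:
                raise ValueError("empty chromosome name")
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
            if chrom in self._lengths:
                raise ValueError(f"duplicate chromosome {chrom!r}")
            self._lengths[chrom] = length

    @property
    def chroms(self) -> list[str]:
        return list(self._lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __getitem__(self, chrom: str) -> int:
        return self._lengths[chrom]

    def __iter__(self):
        return iter(self._lengths.items())

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeTable) and self._lengths == other._lengths

    def __repr__(self) -> str:
        return f"GenomeTable({self._lengths!r})"

    @property
    def total_bp(self) -> int:
        return sum(self._lengths.values())


class SampleTable:
    """Sample metadata: one row per sample with tissue and donor labels."""

    REQUIRED = ("sample_id", "tissue", "donor")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        df = df.loc[:, list(self.REQUIRED)].astype(str).reset_index(drop=True)
        if df["sample_id"].duplicated().any():
            dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
            raise ValueError(f"duplicate sample ids: {dups}")
        for col in self.REQUIRED:
            if (df[col].str.len() == 0).any() or df[col].isin(["nan"]).any():
                raise ValueError(f"empty label in column {col!r}")
        self.df = df

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    @property
    def tissues(self) -> list[str]:
        """Tissue labels in first-appearance order."""
        return list(dict.fromkeys(self.df["tissue"]))

    def samples_of(self, tissue: str) -> list[str]:
        sel = self.df.loc[self.df["tissue"] == tissue, "sample_id"]
        if sel.empty:
            raise KeyError(f"tissue {tissue!r} has no samples")
        return sel.tolist()


class SignalMatrix:
    """Gene × sample matrix of non-negative, RPKM-like abundance values."""

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            dups = sorted(values.index[values.index.duplicated()].unique())
            raise ValueError(f"duplicate gene ids: {dups}")
        if values.columns.duplicated().any():
            dups = sorted(values.columns[values.columns.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at gene {values.index[i]!r}, sample {values.columns[j]!r}"
            )
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative value {arr[i, j]} at gene {values.index[i]!r}, "
                f"sample {values.columns[j]!r}"
            )
        self.df = values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return self.df.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.df.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def __eq__(self, other) -> bool:
        return isinstance(other, SignalMatrix) and self.df.equals(other.df)


@dataclass(frozen=True)
class GeneModel:
    """A gene span with a collapsed (union) exon structure.

    ``exons`` are sorted, pairwise disjoint, and contained in ``[start, end)``.
    TSS is ``start`` on '+' and ``end`` on '-'.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: unknown strand {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id!r}: start {self.start} >= end {self.end}")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id!r}: exon ({s},{e}) outside gene span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id!r}: exons overlap or unsorted at ({s},{e})")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def length(self) -> int:
        return self.end - self.start

    def exon_union_bp(self) -> int:
        return sum(e - s for s, e in self.exons)


def _validate_intervals(df: pd.DataFrame, genome: GenomeTable, what: str) -> pd.DataFrame:
    df = df.reset_index(drop=True)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    bad = df["start"] >= df["end"]
    if bad.any():
        row = df[bad].iloc[0]
        raise ValueError(f"{what}: empty/inverted interval {row['chrom']}:{row['start']}-{row['end']}")
    if (df["start"] < 0).any():
        raise ValueError(f"{what}: negative start coordinate")
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in genome:
            raise ValueError(f"{what}: chromosome {chrom!r} not in genome table")
        if int(sub["end"].max()) > genome[chrom]:
            raise ValueError(
                f"{what}: interval exceeds length of {chrom} ({genome[chrom]} bp)"
            )
    return df


class IntervalSet:
    """A set of genomic intervals (e.g. called peaks) on a declared genome."""

    def __init__(self, df: pd.DataFrame, genome: GenomeTable):
        cols = ["chrom", "start", "end"] + (["score"] if "score" in df.columns else [])
        self.df = _validate_intervals(df.loc[:, cols].copy(), genome, "interval set")
        self.genome = genome

    def __len__(self) -> int:
        return len(self.df)

    @property
    def total_bp(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def sorted(self) -> "IntervalSet":
        return IntervalSet(
            self.df.sort_values(["chrom", "start", "end"], kind="stable"), self.genome
        )


class Segmentation:
    """Labelled, non-overlapping intervals partitioning (part of) a genome."""

    def __init__(self, df: pd.DataFrame, vocabulary: Sequence[str], genome: GenomeTable):
        vocabulary = list(vocabulary)
        if len(set(vocabulary)) != len(vocabulary):
            raise ValueError("segmentation vocabulary has duplicates")
        df = df.loc[:, ["chrom", "start", "end", "label"]].copy()
        df = _validate_intervals(df, genome, "segmentation")
        unknown = set(df["label"]) - set(vocabulary)
        if unknown:
            raise ValueError(f"segmentation labels outside vocabulary: {sorted(unknown)}")
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if (starts[1:] < ends[:-1]).any():
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValueError(
                    f"segmentation: overlapping intervals on {chrom} near position {starts[i + 1]}"
                )
        self.df = df
        self.vocabulary = vocabulary
        self.genome = genome

    def label_bp(self) -> pd.Series:
        """Total bp per label, indexed in vocabulary order (absent labels → 0)."""
        bp = (self.df["end"] - self.df["start"]).groupby(self.df["label"]).sum()
        return bp.reindex(self.vocabulary, fill_value=0).astype(np.int64)

    @property
    def total_bp(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    def per_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """chrom → (starts, ends, label_codes) sorted by start; codes index vocabulary."""
        code = {lab: i for i, lab in enumerate(self.vocabulary)}
        out = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            out[chrom] = (
                sub["start"].to_numpy(np.int64),
                sub["end"].to_numpy(np.int64),
                np.array([code[l] for l in sub["label"]], dtype=np.int64),
            )
        return out


class CoverageTrack:
    """Fixed-bin-size, per-chromosome non-negative signal arrays."""

    def __init__(self, bin_size: int, genome: GenomeTable, data: Mapping[str, np.ndarray]):
        bin_size = int(bin_size)
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.bin_size = bin_size
        self.genome = genome
        self.data: dict[str, np.ndarray] = {}
        for chrom, length in genome:
            nbins = -(-length // bin_size)
            arr = np.asarray(data.get(chrom, np.zeros(nbins)), dtype=float)
            if arr.shape != (nbins,):
                raise ValueError(
                    f"track for {chrom}: expected {nbins} bins, got {arr.shape}"
                )
            if (arr < 0).any():
                raise ValueError(f"track for {chrom}: negative values")
            self.data[chrom] = arr

    def interval_mean(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean signal over [start, end); clipped to the chromosome."""
        if start >= end:
            raise ValueError("empty interval")
        length = self.genome[chrom]
        start, end = max(0, start), min(end, length)
        if start >= end:
            return float("nan")
        bs = self.bin_size
        arr = self.data[chrom]
        i0, i1 = start // bs, -(-end // bs)
        idx = np.arange(i0, i1)
        lo = np.maximum(idx * bs, start)
        hi = np.minimum((idx + 1) * bs, end)
        w = (hi - lo).astype(float)
        return float(np.dot(arr[i0:i1], w) / w.sum())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CoverageTrack)
            and self.bin_size == other.bin_size
            and self.genome == other.genome
            and all(np.array_equal(self.data[c], other.data[c]) for c in self.data)
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_genome_table(path) -> GenomeTable:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], dtype={0: str})
    return GenomeTable(dict(zip(df["chrom"], df["length"])))


def write_genome_table(genome: GenomeTable, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome:
            fh.write(f"{chrom}\t{length}\n")


def read_sample_table(path) -> SampleTable:
    return SampleTable(pd.read_csv(path, sep="\t", dtype=str))


def write_sample_table(table: SampleTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path, sample_table_path=None) -> SignalMatrix | tuple[SignalMatrix, SampleTable]:
    """Read a gene × sample TSV (first column gene ids, header sample ids).

    With ``sample_table_path``, also read the sample table and require its
    sample set to match the matrix columns exactly.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    matrix = SignalMatrix(df)
    if sample_table_path is None:
        return matrix
    table = read_sample_table(sample_table_path)
    in_matrix, in_table = set(matrix.sample_ids), set(table.sample_ids)
    if in_matrix != in_table:
        only_m = sorted(in_matrix - in_table)
        only_t = sorted(in_table - in_matrix)
        raise ValueError(
            f"sample mismatch: only in matrix {only_m}; only in sample table {only_t}"
        )
    return matrix, table


def write_matrix_tsv(matrix: SignalMatrix, path) -> None:
    matrix.df.to_csv(path, sep="\t", index_label="gene_id")


def read_bed(path, genome: GenomeTable) -> IntervalSet:
    """Read BED3/BED4/BED5; a 5th numeric column (or numeric 4th) becomes ``score``."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    if df.shape[1] >= 5:
        df["score"] = pd.to_numeric(df[4], errors="coerce")
    elif df.shape[1] == 4 and pd.api.types.is_numeric_dtype(df[3]):
        df["score"] = df[3].astype(float)
    keep = ["chrom", "start", "end"] + (["score"] if "score" in df.columns else [])
    return IntervalSet(df.loc[:, keep], genome)


def write_bed(intervals: IntervalSet, path) -> None:
    intervals.df.to_csv(path, sep="\t", header=False, index=False)


def read_segmentation(path, vocabulary: Sequence[str], genome: GenomeTable) -> Segmentation:
    """Read BED4 with the label in column 4."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "label"], usecols=[0, 1, 2, 3],
        dtype={"chrom": str, "label": str},
    )
    return Segmentation(df, vocabulary, genome)


def write_segmentation(seg: Segmentation, path) -> None:
    seg.df.to_csv(path, sep="\t", header=False, index=False)


def _merge_exons(exons: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    merged: list[list[int]] = []
    for s, e in sorted(exons):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def _read_bed12(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str, 3: str})
    if df.shape[1] < 12:
        raise ValueError("BED12 requires 12 columns")
    genes = []
    for row in df.itertuples(index=False):
        chrom, start, end, name, _score, strand = row[0], int(row[1]), int(row[2]), row[3], row[4], row[5]
        sizes = [int(x) for x in str(row[10]).rstrip(",").split(",")]
        offsets = [int(x) for x in str(row[11]).rstrip(",").split(",")]
        if len(sizes) != int(row[9]) or len(offsets) != int(row[9]):
            raise ValueError(f"BED12 record {name!r}: block count mismatch")
        exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
        genes.append(GeneModel(name, chrom, start, end, strand, _merge_exons(exons)))
    return genes


def _gtf_attr(attrs: str, key: str) -> str | None:
    for part in attrs.rstrip(";").split(";"):
        part = part.strip()
        if part.startswith(key + " ") or part.startswith(key + "="):
            return part.split(None, 1)[1].strip().strip('"')
    return None


def _read_gtf(path) -> list[GeneModel]:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "source", "feature", "start", "end", "score", "strand", "frame", "attrs"],
        dtype={"chrom": str},
    )
    spans: dict[str, list] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        gid = _gtf_attr(row.attrs, "gene_id")
        if gid is None:
            raise ValueError("GTF record without gene_id attribute")
        # GTF is 1-based closed; convert to 0-based half-open
        start, end = int(row.start) - 1, int(row.end)
        if row.feature == "gene":
            spans[gid] = [row.chrom, start, end, row.strand]
        elif row.feature == "exon":
            exons.setdefault(gid, []).append((start, end))
    genes = []
    for gid, (chrom, start, end, strand) in spans.items():
        ex = _merge_exons(exons.get(gid, [(start, end)]))
        genes.append(GeneModel(gid, chrom, start, end, strand, ex))
    return genes


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from BED12 or minimal GTF (gene/exon features).

    Format is sniffed from the extension (.gtf/.gff → GTF, else BED12).
    Transcript records sharing a gene_id collapse to the exon union.
    """
    suffix = Path(path).suffix.lower()
    if suffix in (".gtf", ".gff"):
        return _read_gtf(path)
    return _read_bed12(path)


def write_bed12(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            exons = g.exons or ((g.start, g.end),)
            sizes = ",".join(str(e - s) for s, e in exons)
            offsets = ",".join(str(s - g.start) for s, e in exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(exons)}\t{sizes}\t{offsets}\n"
            )


def write_gtf(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\thmcmap\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\thmcmap\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def read_bedgraph(path, genome: GenomeTable, bin_size: int) -> CoverageTrack:
    """Bin a bedGraph into fixed bins by length-weighted mean; uncovered bases are 0."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"], dtype={"chrom": str},
    )
    df = _validate_intervals(df, genome, "bedGraph")
    bs = int(bin_size)
    data = {}
    for chrom, length in genome:
        nbins = -(-length // bs)
        acc = np.zeros(nbins)
        sub = df[df["chrom"] == chrom]
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            i0, i1 = s // bs, -(-e // bs)
            idx = np.arange(i0, i1)
            lo = np.maximum(idx * bs, s)
            hi = np.minimum((idx + 1) * bs, e)
            acc[i0:i1] += (hi - lo) * v
        widths = np.minimum((np.arange(nbins) + 1) * bs, length) - np.arange(nbins) * bs
        data[chrom] = acc / widths
    return CoverageTrack(bs, genome, data)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write one record per bin (no run-length merging; trivially re-readable)."""
    with open(path, "w") as fh:
        for chrom, length in track.genome:
            arr = track.data[chrom]
            bs = track.bin_size
            for i, v in enumerate(arr):
                end = min((i + 1) * bs, length)
                fh.write(f"{chrom}\t{i * bs}\t{end}\t{v:.17g}\n")
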