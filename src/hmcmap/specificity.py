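"""Tiered tissue-specificity classification of gene-level signal.

Genes are assigned one of five categories from their per-tissue abundance
(donor-aggregated RPKM-like values), following the Human Protein Atlas style
tiered rules with configurable cutoffs:

* ``tissue_enriched`` — signal in one tissue at least ``fold_cutoff`` times the
  *maximum* of all other tissues;
* ``group_enriched`` — the *mean* over a small group of tissues at least
  ``fold_cutoff`` times the maximum outside the group;
* ``tissue_enhanced`` — signal in one tissue at least ``fold_cutoff`` times the
  *mean* of all other tissues;
* ``not_specific`` / ``low_signal`` otherwise.

Rules are evaluated in decreasing stringency (enriched → group_enriched →
enhanced) and each gene receives exactly one category. The candidate value
(or group mean) must also reach ``abundance_cutoff``; a gene whose maximum
value falls below the cutoff is ``low_signal``.

The defaults used for 5hmC gene-body signal are fold 2 / abundance 10 with
groups of 2–7 tissues; RNA expression conventionally uses fold 4 / abundance 1
(and the HPA uses groups of 2–5).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SampleTable, SignalMatrix

__all__ = [
    "CATEGORIES",
    "SpecificityParams",
    "TissueMatrix",
    "SpecificityCall",
    "aggregate_by_tissue",
    "classify_gene",
    "classify_all",
    "zscore_rows",
    "TissueSpecificityModel",
    "SpecificityResults",
]

CATEGORIES = (
    "tissue_enriched",
    "group_enriched",
    "tissue_enhanced",
    "not_specific",
    "low_signal",
)


@dataclass(frozen=True)
class SpecificityParams:
    """Cutoffs and group-size range for the tiered classifier."""

    fold_cutoff: float = 2.0
    abundance_cutoff: float = 10.0
    group_min: int = 2
    group_max: int = 7
    specific_categories: tuple[str, ...] = ("tissue_enriched", "tissue_enhanced")

    def __post_init__(self):
        if not self.fold_cutoff > 1:
            raise ValueError("fold_cutoff must exceed 1")
        if self.abundance_cutoff < 0:
            raise ValueError("abundance_cutoff must be >= 0")
        if self.group_min < 2:
            raise ValueError("group_min must be >= 2")
        if self.group_max < self.group_min:
            raise ValueError("group_max must be >= group_min")
        unknown = set(self.specific_categories) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")

    @classmethod
    def for_hmc(cls) -> "SpecificityParams":
        return cls(fold_cutoff=2.0, abundance_cutoff=10.0, group_min=2, group_max=7)

    @classmethod
    def for_rna(cls, group_max: int = 5) -> "SpecificityParams":
        return cls(fold_cutoff=4.0, abundance_cutoff=1.0, group_min=2, group_max=group_max)


class TissueMatrix:
    """Gene × tissue matrix of donor-aggregated abundance."""

    def __init__(self, df: pd.DataFrame):
        if df.columns.duplicated().any():
            raise ValueError("duplicate tissue labels")
        if df.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        arr = df.to_numpy(float)
        if (arr < 0).any() or not np.all(np.isfinite(arr)):
            raise ValueError("tissue matrix must be finite and non-negative")
        self.df = df.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return self.df.index.tolist()

    @property
    def tissues(self) -> list[str]:
        return self.df.columns.tolist()


@dataclass(frozen=True)
class SpecificityCall:
    """One gene's category, its target tissue set, and the achieved fold."""

    gene_id: str
    category: str
    target_tissues: tuple[str, ...]
    fold_score: float

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        n = len(self.target_tissues)
        if self.category in ("tissue_enriched", "tissue_enhanced") and n != 1:
            raise ValueError(f"{self.category} requires exactly one target tissue")
        if self.category == "group_enriched" and n < 2:
            raise ValueError("group_enriched requires >= 2 target tissues")
        if self.category in ("not_specific", "low_signal") and n != 0:
            raise ValueError(f"{self.category} must have no target tissues")


def aggregate_by_tissue(
    matrix: SignalMatrix, samples: SampleTable, method: str = "mean"
) -> TissueMatrix:
    """Collapse donor samples to one column per tissue (mean or median)."""
    if method not in ("mean", "median"):
        raise ValueError(f"unknown aggregation method {method!r}")
    missing = set(matrix.sample_ids) - set(samples.sample_ids)
    if missing:
        raise ValueError(f"samples absent from sample table: {sorted(missing)}")
    cols = {}
    for tissue in samples.tissues:
        ids = [s for s in samples.samples_of(tissue) if s in matrix.df.columns]
        if not ids:
            raise ValueError(f"tissue {tissue!r} has no samples in the matrix")
        sub = matrix.df.loc[:, ids]
        cols[tissue] = sub.mean(axis=1) if method == "mean" else sub.median(axis=1)
    return TissueMatrix(pd.DataFrame(cols))


def _fold(num: float, den: float) -> float:
    if den == 0:
        return math.inf if num > 0 else 0.0
    return float(num / den)


def classify_gene(values: Mapping[str, float], params: SpecificityParams) -> SpecificityCall:
    """Classify one gene from its per-tissue abundance map.

    Ties: if several tissues satisfy the enhanced rule the highest-value tissue
    wins (then lexicographic order); qualifying groups prefer the smallest
    size, then the highest mean, realised by testing the top-k tissues sorted
    by descending value with lexicographic tie-break.
    """
    tissues = list(values)
    n = len(tissues)
    if n < 3:
        raise ValueError("classification requires at least 3 tissues")
    if params.group_max >= n:
        raise ValueError(
            f"group_max ({params.group_max}) must be smaller than the number of tissues ({n})"
        )
    v = np.array([float(values[t]) for t in tissues])
    if (v < 0).any() or not np.all(np.isfinite(v)):
        raise ValueError("abundance values must be finite and non-negative")
    gene_id = ""
    fc, ac = params.fold_cutoff, params.abundance_cutoff

    # order: descending value, lexicographic tissue label on ties
    order = sorted(range(n), key=lambda i: (-v[i], tissues[i]))

    # tissue_enriched: only the top-value tissue can reach fold_cutoff > 1
    # against the max of the others (unless all others are zero, in which case
    # the top tissue is still the unique candidate with positive value).
    top = order[0]
    others_max = max((v[i] for i in range(n) if i != top), default=0.0)
    if v[top] >= ac and v[top] >= fc * others_max and v[top] > 0:
        return SpecificityCall(gene_id, "tissue_enriched", (tissues[top],), _fold(v[top], others_max))

    # group_enriched: for each allowed size k, the top-k set maximises the
    # group mean and minimises the maximum outside, so it qualifies whenever
    # any size-k group does. Smallest qualifying size wins.
    for k in range(params.group_min, params.group_max + 1):
        group = order[:k]
        gmean = float(v[group].mean())
        out_max = max((v[i] for i in range(n) if i not in group), default=0.0)
        if gmean >= ac and gmean >= fc * out_max and gmean > 0:
            labels = tuple(sorted(tissues[i] for i in group))
            return SpecificityCall(gene_id, "group_enriched", labels, _fold(gmean, out_max))

    # tissue_enhanced: candidates in descending-value order; first qualifying wins.
    total = float(v.sum())
    for i in order:
        others_mean = (total - v[i]) / (n - 1)
        if v[i] >= ac and v[i] >= fc * others_mean and v[i] > 0:
            return SpecificityCall(gene_id, "tissue_enhanced", (tissues[i],), _fold(v[i], others_mean))

    if v.max() < ac:
        return SpecificityCall(gene_id, "low_signal", (), 0.0)
    return SpecificityCall(gene_id, "not_specific", (), 0.0)


def classify_all(
    tm: TissueMatrix, params: SpecificityParams
) -> tuple[list[SpecificityCall], pd.Series]:
    """Classify every gene; also tally specific genes per target tissue.

    The count table tallies genes whose category is in
    ``params.specific_categories`` under each of their target tissues.
    """
    tissues = tm.tissues
    calls = []
    counts = pd.Series(0, index=tissues, dtype=int)
    for gene_id, row in zip(tm.gene_ids, tm.df.to_numpy()):
        call = classify_gene(dict(zip(tissues, row)), params)
        call = SpecificityCall(gene_id, call.category, call.target_tissues, call.fold_score)
        calls.append(call)
        if call.category in params.specific_categories:
            for t in call.target_tissues:
                counts[t] += 1
    return calls, counts


def zscore_rows(tm: TissueMatrix, gene_subset: Sequence[str] | None = None) -> pd.DataFrame:
    """Row z-scores ((v − mean) / population sd) for heatmap display.

    Constant rows get all-zero z-scores with a warning.
    """
    df = tm.df if gene_subset is None else tm.df.loc[list(gene_subset)]
    arr = df.to_numpy(float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant row(s): z-scores set to 0", UserWarning, stacklevel=2
        )
    sd[flat] = 1.0
    z = (arr - mean) / sd
    z[flat[:, None] & np.ones_like(z, bool)] = 0.0
    return pd.DataFrame(z, index=df.index, columns=df.columns)


# ---------------------------------------------------------------------------
# Model / Results presentation
# ---------------------------------------------------------------------------


class TissueSpecificityModel:
    """Tiered specificity classifier bound to a signal matrix.

    Parameters
    ----------
    matrix
        Gene × sample signal matrix (RPKM-like values).
    samples
        Sample → tissue/donor table covering every matrix column.
    params
        Classifier cutoffs; defaults to the 5hmC setting (fold 2, abundance 10).
    aggregate
        Donor aggregation, ``"mean"`` (default) or ``"median"``.
    """

    def __init__(
        self,
        matrix: SignalMatrix,
        samples: SampleTable,
        params: SpecificityParams | None = None,
        aggregate: str = "mean",
    ):
        self.matrix = matrix
        self.samples = samples
        self.params = params or SpecificityParams()
        self.aggregate = aggregate

    @classmethod
    def from_dataframe(
        cls, values: pd.DataFrame, samples: pd.DataFrame, **kwargs
    ) -> "TissueSpecificityModel":
        return cls(SignalMatrix(values), SampleTable(samples), **kwargs)

    def fit(self) -> "SpecificityResults":
        tm = aggregate_by_tissue(self.matrix, self.samples, self.aggregate)
        calls, counts = classify_all(tm, self.params)
        return SpecificityResults(self, tm, calls, counts)


class SpecificityResults:
    """Classification outcome: per-gene calls, per-tissue counts, heatmap input."""

    def __init__(self, model, tissue_matrix, calls, tissue_counts):
        self.model = model
        self.tissue_matrix = tissue_matrix
        self.calls = calls
        self.tissue_counts = tissue_counts

    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [c.gene_id for c in self.calls],
                "category": [c.category for c in self.calls],
                "target_tissues": [",".join(c.target_tissues) for c in self.calls],
                "fold_score": [c.fold_score for c in self.calls],
            }
        )

    def specific_genes(self, tissue: str | None = None) -> list[str]:
        """Gene ids with a specific category, optionally restricted to one tissue."""
        keep = self.model.params.specific_categories
        out = []
        for c in self.calls:
            if c.category in keep and (tissue is None or tissue in c.target_tissues):
                out.append(c.gene_id)
        return out

    def category_counts(self) -> pd.Series:
        s = pd.Series([c.category for c in self.calls]).value_counts()
        return s.reindex(CATEGORIES, fill_value=0)

    def heatmap_matrix(self) -> pd.DataFrame:
        """Row z-scores of specific genes across tissues (display matrix)."""
        genes = self.specific_genes()
        return zscore_rows(self.tissue_matrix, genes)

    def summary(self) -> str:
        p = self.model.params
        lines = [
            "Tissue specificity classification",
            "=================================",
            f"genes: {len(self.calls)}   tissues: {len(self.tissue_matrix.tissues)}",
            f"fold_cutoff: {p.fold_cutoff}   abundance_cutoff: {p.abundance_cutoff}   "
            f"group sizes: {p.group_min}-{p.group_max}",
            "",
            "category counts:",
        ]
        for cat, cnt in self.category_counts().items():
            lines.append(f"  {cat:<16s} {cnt:>6d}")
        lines.append("")
        lines.append("specific genes per tissue "
                     f"(categories: {', '.join(p.specific_categories)}):")
        for tissue, cnt in self.tissue_counts.items():
            lines.append(f"  {tissue:<20s} {cnt:>6d}")
        return "\n".join(lines)
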