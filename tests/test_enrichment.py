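import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hmcmap import (
    GeneModel,
    GenomeTable,
    IntervalSet,
    Segmentation,
    SegmentationEnrichment,
    build_feature_segmentation,
    cross_tissue_enrichment_matrix,
    overlap_enrichment,
    segmentation_enrichment,
    set_fold_enrichment,
    shuffle_intervals,
)
from hmcmap.enrichment import annotate_peaks
from hmcmap.specificity import SpecificityCall


def _iv(rows, genome):
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]), genome)


def _seg_dict(seg):
    return {
        (r.chrom, r.start, r.end): r.label for r in seg.df.itertuples(index=False)
    }


def test_feature_segmentation_plus_strand_hand_layout():
    genome = GenomeTable({"c": 3000})
    gene = GeneModel("g", "c", 1000, 2000, "+", exons=((1000, 2000),))
    seg = build_feature_segmentation([gene], genome)
    assert _seg_dict(seg) == {
        ("c", 0, 1100): "promoter",
        ("c", 1100, 2000): "exon",
        ("c", 2000, 3000): "intergenic",
    }


def test_feature_segmentation_minus_strand_promoter_orientation():
    genome = GenomeTable({"c": 3000})
    gene = GeneModel("g", "c", 1000, 2000, "-", exons=((1000, 2000),))
    seg = build_feature_segmentation([gene], genome)
    d = _seg_dict(seg)
    assert d[("c", 1900, 3000)] == "promoter"  # TSS at 2000, window [-100, +1000)
    assert d[("c", 1000, 1900)] == "exon"


def test_feature_segmentation_empty_genome_is_intergenic():
    genome = GenomeTable({"c": 500})
    seg = build_feature_segmentation([], genome)
    assert _seg_dict(seg) == {("c", 0, 500): "intergenic"}
    assert seg.total_bp == 500


def test_feature_segmentation_intron_and_coverage():
    genome = GenomeTable({"c": 10_000})
    gene = GeneModel("g", "c", 3000, 6000, "+", exons=((3000, 3500), (5000, 6000)))
    seg = build_feature_segmentation([gene], genome)
    bp = dict(seg.label_bp())
    assert seg.total_bp == 10_000  # exact partition
    assert bp["intron"] == 1500
    assert bp["promoter"] == 1100


def test_segmentation_enrichment_toy_fold():
    genome = GenomeTable({"c": 1000})
    seg = Segmentation(
        pd.DataFrame(
            {"chrom": ["c", "c", "c"], "start": [0, 100, 500], "end": [100, 500, 1000],
             "label": ["promoter", "exon", "intergenic"]}
        ),
        ["promoter", "exon", "intergenic"],
        genome,
    )
    peaks = _iv([("c", 20, 70)], genome)
    res = segmentation_enrichment(peaks, seg).set_index("label")
    assert res.loc["promoter", "observed_fraction"] == 1.0
    assert res.loc["promoter", "expected_fraction"] == pytest.approx(0.1)
    assert res.loc["promoter", "fold"] == pytest.approx(10.0)
    assert res["observed_fraction"].sum() == pytest.approx(1.0)
    assert res["expected_fraction"].sum() == pytest.approx(1.0)


def test_whole_genome_peak_set_has_unit_folds():
    genome = GenomeTable({"c1": 4000, "c2": 2500})
    genes = [GeneModel("g", "c1", 1500, 3000, "+", exons=((1500, 2200),))]
    seg = build_feature_segmentation(genes, genome)
    peaks = _iv([("c1", 0, 4000), ("c2", 0, 2500)], genome)
    res = segmentation_enrichment(peaks, seg)
    present = res["expected_fraction"] > 0
    assert np.allclose(res.loc[present, "fold"], 1.0)


def test_peak_majority_mode_assigns_dominant_label():
    genome = GenomeTable({"c": 1000})
    seg = Segmentation(
        pd.DataFrame({"chrom": ["c", "c"], "start": [0, 100], "end": [100, 1000],
                      "label": ["a", "b"]}),
        ["a", "b"],
        genome,
    )
    # 30 bp in 'a', 70 bp in 'b' -> majority 'b'
    peaks = _iv([("c", 70, 170)], genome)
    res = segmentation_enrichment(peaks, seg, mode="peak_majority").set_index("label")
    assert res.loc["b", "observed_fraction"] == 1.0
    ann = annotate_peaks(peaks, seg)
    assert ann["label"].tolist() == ["b"]


@pytest.mark.skipif(shutil.which("bedtools") is None, reason="bedtools not on PATH")
def test_bp_overlap_matches_bedtools(tmp_path):
    """Per-label peak bp agrees with an independent bedtools intersect run."""
    rng = np.random.default_rng(12)
    genome = GenomeTable({"c1": 50_000, "c2": 30_000})
    genes = [
        GeneModel("gA", "c1", 10_000, 20_000, "+", exons=((10_000, 12_000), (15_000, 20_000))),
        GeneModel("gB", "c2", 5_000, 12_000, "-", exons=((5_000, 12_000),)),
    ]
    seg = build_feature_segmentation(genes, genome)
    starts = rng.integers(0, 45_000, size=60)
    peaks = _iv(
        [("c1" if i % 2 else "c2", int(s % 25_000), int(s % 25_000) + 400) for i, s in enumerate(starts)],
        genome,
    )
    seg_path, peak_path = tmp_path / "seg.bed", tmp_path / "peaks.bed"
    seg.df.to_csv(seg_path, sep="\t", header=False, index=False)
    peaks.df.to_csv(peak_path, sep="\t", header=False, index=False)
    out = subprocess.run(
        ["bedtools", "intersect", "-a", peak_path, "-b", seg_path, "-wo"],
        capture_output=True, text=True, check=True,
    ).stdout
    bt = {}
    for line in out.strip().splitlines():
        f = line.split("\t")
        bt[f[6]] = bt.get(f[6], 0) + int(f[-1])
    res = segmentation_enrichment(peaks, seg).set_index("label")
    total = peaks.total_bp
    for label in seg.vocabulary:
        assert res.loc[label, "observed_fraction"] * total == pytest.approx(bt.get(label, 0))


def test_shuffle_preserves_lengths_and_is_seeded():
    genome = GenomeTable({"c1": 10_000, "c2": 8_000})
    peaks = _iv([("c1", 0, 500), ("c1", 900, 1000), ("c2", 10, 400)], genome)
    a = shuffle_intervals(peaks, genome, seed=42)
    b = shuffle_intervals(peaks, genome, seed=42)
    assert a.df.equals(b.df)
    assert sorted(a.lengths()) == sorted(peaks.lengths())
    assert a.df["chrom"].tolist() == peaks.df["chrom"].tolist()  # same-chromosome default
    c = shuffle_intervals(peaks, genome, seed=43)
    assert not c.df.equals(a.df)


def test_shuffle_respects_excluded_regions():
    genome = GenomeTable({"c": 10_000})
    peaks = _iv([("c", 0, 100)] * 50, genome)
    excluded = _iv([("c", 0, 9_000)], genome)
    shuf = shuffle_intervals(peaks, genome, seed=0, excluded=excluded)
    assert (shuf.df["start"] >= 9_000).all()


def test_shuffle_start_positions_uniform():
    """Chi-square goodness of fit of shuffled starts on a one-chromosome genome."""
    genome = GenomeTable({"c": 1_000})
    peaks = _iv([("c", 0, 100)] * 2_000, genome)
    shuf = shuffle_intervals(peaks, genome, seed=9)
    counts, _ = np.histogram(shuf.df["start"], bins=10, range=(0, 901))
    assert stats.chisquare(counts).pvalue > 0.01


def test_overlap_enrichment_worked_identity():
    res = overlap_enrichment(6, 100, 10, 20)
    assert res["fold"] == pytest.approx(3.0)


def test_set_fold_enrichment_identities_and_symmetry():
    U = [f"g{i}" for i in range(100)]
    A, B = set(U[:10]), set(U[5:25])
    res = set_fold_enrichment(A, B, U)
    assert res["fold"] == pytest.approx(
        set_fold_enrichment(B, A, U)["fold"]
    )  # symmetric in A and B
    same = set_fold_enrichment(A, A, U)
    assert same["fold"] == pytest.approx(len(U) / len(A))
    with pytest.raises(ValueError, match="non-empty"):
        set_fold_enrichment(set(), B, U)
    with pytest.raises(ValueError, match="subset"):
        set_fold_enrichment({"zzz"}, B, U)


def test_random_sets_fold_near_one():
    rng = np.random.default_rng(17)
    U = [f"g{i}" for i in range(2000)]
    folds = [
        set_fold_enrichment(
            rng.choice(U, 100, replace=False), rng.choice(U, 400, replace=False), U
        )["fold"]
        for _ in range(200)
    ]
    folds = np.array(folds)
    se = folds.std(ddof=1) / np.sqrt(len(folds))
    assert abs(folds.mean() - 1.0) < 3 * se


def _call(gene, cat, tissues):
    fold = 0.0 if cat in ("not_specific", "low_signal") else 5.0
    return SpecificityCall(gene, cat, tissues, fold)


def test_cross_tissue_matrix_identity_case():
    U = [f"g{i}" for i in range(100)]
    calls_a = [_call(U[0], "tissue_enriched", ("A",)), _call(U[1], "tissue_enriched", ("B",))]
    calls_b = list(calls_a)
    mat = cross_tissue_enrichment_matrix(calls_a, calls_b, U)
    assert mat.loc["A", "A"] == pytest.approx(100.0)  # |U|/|B_t| with 1 gene
    assert mat.loc["A", "B"] == 0.0
    # permuting tissue order permutes rows/columns identically
    mat2 = mat.loc[["B", "A"], ["B", "A"]]
    assert mat2.loc["A", "A"] == mat.loc["A", "A"]


def test_cross_tissue_matrix_missing_tissues_are_nan():
    U = [f"g{i}" for i in range(50)]
    calls_a = [_call(U[0], "tissue_enriched", ("A",))]
    calls_b = [_call(U[1], "tissue_enriched", ("B",))]
    mat = cross_tissue_enrichment_matrix(calls_a, calls_b, U)
    assert np.isnan(mat.loc["A", "A"])  # no B-side genes for tissue A
    assert mat.loc["A", "B"] == 0.0
    with pytest.raises(ValueError, match="universe"):
        cross_tissue_enrichment_matrix(calls_a, calls_b, U[2:])


def test_model_fit_with_shuffle_null():
    genome = GenomeTable({"c": 20_000})
    genes = [GeneModel("g", "c", 5_000, 10_000, "+", exons=((5_000, 10_000),))]
    seg = build_feature_segmentation(genes, genome)
    peaks = _iv([("c", 5_100, 5_400), ("c", 6_000, 6_200), ("c", 12_000, 12_300)], genome)
    res = SegmentationEnrichment(peaks, seg).fit(shuffles=25, seed=3)
    frame = res.to_frame()
    assert {"null_mean", "null_sd", "empirical_p"} <= set(frame.columns)
    assert ((frame["empirical_p"] > 0) & (frame["empirical_p"] <= 1)).all()
    assert "Segmentation enrichment" in res.summary()
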