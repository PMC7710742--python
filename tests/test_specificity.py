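import math

import numpy as np
import pandas as pd
import pytest

from _oracle import brute_force_classify, random_abundance_vector
from hmcmap import (
    SpecificityParams,
    TissueSpecificityModel,
    aggregate_by_tissue,
    classify_all,
    classify_gene,
    zscore_rows,
)
from hmcmap.specificity import TissueMatrix


HMC = SpecificityParams(fold_cutoff=2, abundance_cutoff=10, group_min=2, group_max=2)


@pytest.mark.parametrize(
    "values,params,category,targets,fold",
    [
        ({"A": 40, "B": 10, "C": 10}, HMC, "tissue_enriched", ("A",), 4.0),
        ({"A": 30, "B": 28, "C": 5}, HMC, "group_enriched", ("A", "B"), 29 / 5),
        (
            {"A": 20, "B": 11, "C": 9, "D": 9},
            SpecificityParams(2, 10, 2, 3),
            "tissue_enhanced",
            ("A",),
            20 / ((11 + 9 + 9) / 3),
        ),
        ({"A": 5, "B": 1, "C": 1}, HMC, "low_signal", (), 0.0),
        ({"A": 12, "B": 11, "C": 9}, HMC, "not_specific", (), 0.0),
        # all other tissues zero: rule fires with infinite fold
        ({"A": 15, "B": 0, "C": 0}, HMC, "tissue_enriched", ("A",), math.inf),
        # boundary: exactly twofold counts ("at least twofold")
        ({"A": 20, "B": 10, "C": 4}, HMC, "tissue_enriched", ("A",), 2.0),
    ],
)
def test_classify_gene_rules(values, params, category, targets, fold):
    call = classify_gene(values, params)
    assert call.category == category
    assert call.target_tissues == targets
    assert call.fold_score == pytest.approx(fold)


def test_classify_gene_input_validation():
    with pytest.raises(ValueError, match="3 tissues"):
        classify_gene({"A": 1, "B": 2}, HMC)
    with pytest.raises(ValueError, match="group_max"):
        classify_gene({"A": 1, "B": 2, "C": 3}, SpecificityParams(2, 10, 2, 3))


def test_classifier_matches_brute_force_enumeration():
    """Exhaustive enumeration of all tissues and groups agrees with the implementation."""
    rng = np.random.default_rng(2024)
    for trial in range(300):
        n = int(rng.integers(4, 11))
        params = SpecificityParams(
            fold_cutoff=float(rng.choice([1.5, 2.0, 4.0])),
            abundance_cutoff=float(rng.choice([0.0, 1.0, 10.0])),
            group_min=2,
            group_max=int(rng.integers(2, n)),
        )
        values = random_abundance_vector(rng, n)
        call = classify_gene(values, params)
        cat, targets, fold = brute_force_classify(values, params)
        assert call.category == cat, (values, params)
        assert call.target_tissues == targets, (values, params)
        assert call.fold_score == pytest.approx(fold), (values, params)


def test_classification_equivariant_under_tissue_relabeling():
    rng = np.random.default_rng(5)
    params = SpecificityParams(2, 1, 2, 3)
    values = random_abundance_vector(rng, 6)
    call = classify_gene(values, params)
    mapping = {t: f"x_{t}" for t in values}
    permuted = {mapping[t]: v for t, v in reversed(list(values.items()))}
    call2 = classify_gene(permuted, params)
    assert call2.category == call.category
    assert set(call2.target_tissues) == {mapping[t] for t in call.target_tissues}


def test_scaling_behaviour():
    """Fold comparisons are scale-free: without an abundance gate the call is
    scale-invariant; with one, scaling up can only release abundance-gated
    rules (never create low_signal), and an unchanged category keeps its fold."""
    rng = np.random.default_rng(6)
    free = SpecificityParams(2, 0, 2, 3)
    gated = SpecificityParams(2, 10, 2, 3)
    for _ in range(50):
        values = random_abundance_vector(rng, 6)
        scaled_values = {t: 10 * v for t, v in values.items()}
        a, b = classify_gene(values, free), classify_gene(scaled_values, free)
        assert (a.category, a.target_tissues) == (b.category, b.target_tissues)
        assert b.fold_score == pytest.approx(a.fold_score)
        a, b = classify_gene(values, gated), classify_gene(scaled_values, gated)
        assert b.category != "low_signal"
        if a.category == b.category:
            assert b.fold_score == pytest.approx(a.fold_score) or a.category in (
                "low_signal",
                "not_specific",
            )


def test_aggregate_by_tissue(small_matrix, small_samples):
    tm = aggregate_by_tissue(small_matrix, small_samples)
    assert tm.df.loc["g1", "A"] == pytest.approx(3.0)  # mean of 2 and 4
    assert tm.df.loc["g2", "B"] == pytest.approx(10.0)
    # permuting sample columns changes nothing
    shuffled = small_matrix.df.iloc[:, [3, 1, 0, 2]]
    from hmcmap import SignalMatrix

    tm2 = aggregate_by_tissue(SignalMatrix(shuffled), small_samples)
    assert tm2.df.equals(tm.df)


def test_classify_all_counts_specific_categories():
    tm = TissueMatrix(
        pd.DataFrame(
            {
                "A": [40.0, 30.0, 20.0],
                "B": [10.0, 28.0, 11.0],
                "C": [10.0, 5.0, 9.0],
                "D": [10.0, 5.0, 9.0],
            },
            index=["enr", "grp", "enh"],
        )
    )
    params = SpecificityParams(2, 10, 2, 3)
    calls, counts = classify_all(tm, params)
    by_gene = {c.gene_id: c.category for c in calls}
    assert by_gene == {
        "enr": "tissue_enriched",
        "grp": "group_enriched",
        "enh": "tissue_enhanced",
    }
    # group calls are not counted as tissue-specific
    assert counts["A"] == 2
    assert counts["B"] == 0


def test_classify_all_constant_matrix_yields_nothing_specific():
    tm = TissueMatrix(pd.DataFrame(np.full((5, 4), 20.0), columns=list("ABCD")))
    calls, counts = classify_all(tm, SpecificityParams(2, 10, 2, 2))
    assert all(c.category == "not_specific" for c in calls)
    assert counts.sum() == 0


def test_zscore_rows_population_sd_and_centering():
    tm = TissueMatrix(pd.DataFrame({"A": [0.0, 7.0], "B": [10.0, 9.0]}, index=["g1", "g2"]))
    z = zscore_rows(tm)
    assert z.loc["g1"].tolist() == pytest.approx([-1.0, 1.0])
    assert abs(z.sum(axis=1)).max() < 1e-9


def test_zscore_constant_row_warns_and_zeroes():
    tm = TissueMatrix(pd.DataFrame({"A": [5.0], "B": [5.0], "C": [5.0]}, index=["g"]))
    with pytest.warns(UserWarning, match="constant"):
        z = zscore_rows(tm)
    assert np.all(z.to_numpy() == 0.0)


def test_model_fit_summary_and_specific_genes(small_matrix, small_samples):
    # only 2 tissues -> must raise through classify_gene
    with pytest.raises(ValueError, match="3 tissues"):
        TissueSpecificityModel(small_matrix, small_samples, HMC).fit()


def test_model_end_to_end_summary():
    rng = np.random.default_rng(1)
    genes = [f"g{i}" for i in range(20)]
    tissues = ["A", "B", "C", "D"]
    rows = rng.lognormal(3, 0.1, size=(20, 8))
    rows[0, 0:2] *= 6  # plant an A-enriched gene (samples A_d1, A_d2)
    samples = pd.DataFrame(
        {
            "sample_id": [f"{t}_d{d}" for t in tissues for d in (1, 2)],
            "tissue": [t for t in tissues for _ in (1, 2)],
            "donor": ["d1", "d2"] * 4,
        }
    )
    model = TissueSpecificityModel.from_dataframe(
        pd.DataFrame(rows, index=genes, columns=samples["sample_id"]),
        samples,
        params=SpecificityParams(2, 10, 2, 2),
    )
    res = model.fit()
    assert "tissue_enriched" in res.summary()
    assert res.specific_genes("A") == ["g0"]
    assert res.heatmap_matrix().shape[1] == 4
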