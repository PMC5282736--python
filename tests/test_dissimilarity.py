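"""Gower / MORD / Hamming dissimilarity under pairwise deletion."""

import numpy as np
import pytest

from morphospace import (
    CharacterMatrix,
    DissimilarityMatrix,
    INAPPLICABLE,
    MISSING,
    SyntheticSpec,
    UndefinedDistanceError,
    distance_completeness_report,
    generate_matrix,
    pairwise_dissimilarity,
)


@pytest.mark.parametrize(
    "row_a, row_b, expected",
    [
        ([0, 1, 1], [0, 1, 1], 0.0),  # identical rows
        ([0, 1, 1], [1, 0, 0], 1.0),  # all comparable, all mismatch
        # pairwise deletion leaves only the first character comparable
        # (2nd inapplicable in B, 3rd missing in A); it matches
        ([0, 1, MISSING], [0, INAPPLICABLE, 1], None),
    ],
)
@pytest.mark.parametrize("method", ["gower", "mord", "hamming"])
def test_hand_examples_unordered(row_a, row_b, expected, method):
    m = CharacterMatrix(["A", "B"], [row_a, row_b], alphabet=[0, 1])
    d = pairwise_dissimilarity(m, method=method)
    value = d.values[0, 1]
    if expected is None:
        assert value == pytest.approx(0.0)
        assert d.comparable_counts[0, 1] == 1
    else:
        assert value == pytest.approx(expected)
        assert d.comparable_counts[0, 1] == 3


def test_gower_vs_mord_with_ordered_characters():
    """Hand-derived: char1 has observed range 2 (ordered), char2 range 1.
    A=(0,0), B=(1,1): gower = (1/2 + 1/1)/2 = 0.75; mord = (1+1)/(2+1)."""
    m = CharacterMatrix(
        ["A", "B", "C"],
        [[0, 0], [1, 1], [2, 0]],
        ordering=[True, True],
    )
    gower = pairwise_dissimilarity(m, method="gower").values[0, 1]
    mord = pairwise_dissimilarity(m, method="mord").values[0, 1]
    hamming = pairwise_dissimilarity(m, method="hamming").values[0, 1]
    assert gower == pytest.approx(0.75)
    assert mord == pytest.approx(2 / 3)
    assert hamming == pytest.approx(1.0)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_indices_coincide_on_unordered_matrices(seed):
    """Gower = Hamming = MORD when every character is unordered (all
    per-character maxima are 1)."""
    matrix, _, _ = generate_matrix(
        SyntheticSpec(n_groups=2, taxa_per_group=6, n_characters=30,
                      states_per_character=3, missing_rate=0.2, seed=seed)
    )
    ds = {
        meth: pairwise_dissimilarity(matrix, method=meth).values
        for meth in ("gower", "mord", "hamming")
    }
    assert np.allclose(ds["gower"], ds["mord"], equal_nan=True)
    assert np.allclose(ds["gower"], ds["hamming"], equal_nan=True)


@pytest.mark.parametrize("seed", [0, 1])
def test_relabelling_invariance_unordered(random_matrix_factory, seed):
    """Distances over unordered characters only depend on state identity,
    not on which integer labels the states carry."""
    m = random_matrix_factory(seed, n_states=3)
    rng = np.random.default_rng(seed + 100)
    perms = [rng.permutation(3) for _ in range(m.n_characters)]

    def relabel(cell, j):
        if cell is MISSING or cell is INAPPLICABLE:
            return cell
        if isinstance(cell, frozenset):
            return frozenset(int(perms[j][s]) for s in cell)
        return int(perms[j][cell])

    cells = [
        [relabel(m.cell(i, j), j) for j in range(m.n_characters)]
        for i in range(m.n_taxa)
    ]
    m2 = CharacterMatrix(m.taxon_labels, cells, alphabet=range(3))
    d1 = pairwise_dissimilarity(m, method="mord").values
    d2 = pairwise_dissimilarity(m2, method="mord").values
    assert np.allclose(d1, d2, equal_nan=True)


def test_polymorphism_rules():
    # unordered: {0,1} vs {1} -> min 0, mean 0.5
    m = CharacterMatrix(["A", "B"], [[frozenset({0, 1})], [1]])
    assert pairwise_dissimilarity(m, polymorphism_rule="min").values[0, 1] == 0.0
    assert pairwise_dissimilarity(m, polymorphism_rule="mean").values[
        0, 1
    ] == pytest.approx(0.5)
    # ordered: {0,2} vs {1} -> min |a-b| = 1, mean = 1; range is 2
    m2 = CharacterMatrix(
        ["A", "B"], [[frozenset({0, 2})], [1]], ordering=[True]
    )
    assert pairwise_dissimilarity(
        m2, method="mord", polymorphism_rule="min"
    ).values[0, 1] == pytest.approx(0.5)


def test_undefined_pair_flagged_and_fails_fast():
    m = CharacterMatrix(
        ["A", "B"], [[0, MISSING], [MISSING, 1]], alphabet=[0, 1]
    )
    d = pairwise_dissimilarity(m)
    assert np.isnan(d.values[0, 1])
    assert d.undefined_pairs() == [("A", "B")]
    with pytest.raises(UndefinedDistanceError):
        d.require_complete()


def test_matrix_invariants(preset_data):
    matrix, _, _ = preset_data
    d = pairwise_dissimilarity(matrix)
    assert np.allclose(np.diag(d.values), 0.0)
    assert np.allclose(d.values, d.values.T)
    assert np.nanmax(d.values) <= 1.0 and np.nanmin(d.values) >= 0.0
    assert d.comparable_counts.max() <= matrix.n_characters


def test_completeness_report_flags_sparse_taxon():
    spec = SyntheticSpec(n_groups=2, taxa_per_group=5, n_characters=40,
                         missing_rate=0.05, n_outlier_taxa=1,
                         outlier_missing_rate=0.9, seed=3)
    matrix, _, truth = generate_matrix(spec)
    d = pairwise_dissimilarity(matrix)
    report = distance_completeness_report(d, min_comparable=5)
    per_taxon = report["per_taxon"]
    assert per_taxon["mean_comparable"].idxmin() == truth["outlier_taxa"][0]
    # brute-force comparable count for one pair
    i, j = 0, 1
    brute = sum(
        matrix.cell(i, k) not in (MISSING, INAPPLICABLE)
        and matrix.cell(j, k) not in (MISSING, INAPPLICABLE)
        for k in range(matrix.n_characters)
    )
    assert d.comparable_counts[i, j] == brute


def test_completeness_report_rejects_single_taxon():
    d = DissimilarityMatrix(("A",), np.zeros((1, 1)), np.zeros((1, 1), int))
    with pytest.raises(ValueError, match="at least 2"):
        distance_completeness_report(d)


def test_exports(tmp_path, preset_data):
    matrix, _, _ = preset_data
    d = pairwise_dissimilarity(matrix)
    d.to_csv(tmp_path / "d.csv")
    d.to_phylip(tmp_path / "d.phy")
    assert (tmp_path / "d.phy").read_text().splitlines()[0] == str(d.n_taxa)
    import pandas as pd

    back = pd.read_csv(tmp_path / "d.csv", index_col=0)
    assert np.allclose(back.to_numpy(), d.values, atol=1e-5)
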