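"""Neighbour joining, taxon deduplication and k-means assessment."""

import io

import numpy as np
import pytest
from skbio import TreeNode
from skbio.tree import nj as skbio_nj
from skbio import DistanceMatrix as SkbioDM

from morphospace import (
    DissimilarityMatrix,
    KMeansAssessment,
    NeighborJoining,
    deduplicate,
    generate_point_clouds,
    neighbour_joining,
)


def _dm(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = tuple(labels or (chr(65 + i) for i in range(len(values))))
    return DissimilarityMatrix(labels, values,
                               np.full(values.shape, 10, dtype=int))


# ----------------------------------------------------------------------
# deduplication
# ----------------------------------------------------------------------
def test_deduplicate_identity_when_no_close_pair():
    d = _dm([[0, 0.5, 0.6], [0.5, 0, 0.7], [0.6, 0.7, 0]])
    reduced, merges = deduplicate(d, tolerance=0.1)
    assert reduced.taxon_labels == d.taxon_labels
    assert all(len(v) == 1 for v in merges.values())


def test_deduplicate_averages_branch_distances():
    # A and B identical; their distances to C are 0.2 and 0.4 -> mean 0.3
    d = _dm([[0, 0.0, 0.2], [0.0, 0, 0.4], [0.2, 0.4, 0]])
    reduced, merges = deduplicate(d, tolerance=0.0)
    assert reduced.taxon_labels == ("A", "C")
    assert merges["A"] == ["A", "B"]
    assert reduced.values[0, 1] == pytest.approx(0.3)


def test_deduplicate_idempotent_and_degenerate():
    d = _dm([[0, 0.0, 0.2], [0.0, 0, 0.4], [0.2, 0.4, 0]])
    reduced, _ = deduplicate(d, tolerance=0.0)
    again, merges = deduplicate(reduced, tolerance=0.0)
    assert again.taxon_labels == reduced.taxon_labels
    assert np.allclose(again.values, reduced.values)
    # all identical -> a single representative; NJ then refuses
    allzero = _dm(np.zeros((3, 3)))
    single, _ = deduplicate(allzero, tolerance=0.0)
    assert single.n_taxa == 1
    with pytest.raises(ValueError, match="at least 3"):
        neighbour_joining(single)


# ----------------------------------------------------------------------
# neighbour joining
# ----------------------------------------------------------------------
def test_nj_three_taxon_closure():
    """d(AB)=2, d(AC)=3, d(BC)=3 solve to branches 1, 1, 2."""
    tree = neighbour_joining(_dm([[0, 2, 3], [2, 0, 3], [3, 3, 0]]))
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(1.0),
                       "C": pytest.approx(2.0)}


def _random_tree_distances(rng, n):
    """Random binary unrooted tree -> (additive distance matrix, newick)."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = round(float(rng.uniform(0.1, 1.0)), 6)
        b.length = round(float(rng.uniform(0.1, 1.0)), 6)
        parent = TreeNode(children=[b, a])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    for x in nodes:
        x.length = round(float(rng.uniform(0.1, 1.0)), 6)
    root = TreeNode(children=nodes)
    labels = [f"t{i}" for i in range(n)]
    dm = root.tip_tip_distances(endpoints=labels)
    values = np.asarray(dm.data)
    return _dm(values, labels), root


@pytest.mark.parametrize("seed", range(15))
def test_nj_recovers_additive_trees(seed):
    """Additivity oracle: NJ on tree path distances returns a tree whose
    path distances equal the input exactly."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 10))
    d, true_tree = _random_tree_distances(rng, n)
    est = NeighborJoining().fit(d)
    got = est.tree_.tip_tip_distances(endpoints=list(d.taxon_labels))
    assert np.allclose(np.asarray(got.data), d.values, atol=1e-6)
    assert est.negative_branch_events_ == 0
    # topology identical to the generating tree
    assert est.tree_.compare_rfd(true_tree) == 0.0


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_nj_agrees_with_skbio(seed):
    """Cross-check against scikit-bio's neighbour joining on random
    (non-additive) symmetric matrices: identical topology."""
    rng = np.random.default_rng(100 + seed)
    n = 8
    v = rng.uniform(0.2, 1.0, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    labels = [f"t{i}" for i in range(n)]
    ours = NeighborJoining().fit(_dm(v, labels)).tree_
    theirs = skbio_nj(SkbioDM(v, ids=labels))
    assert ours.compare_rfd(theirs) == 0.0


def test_nj_invariant_under_taxon_order():
    rng = np.random.default_rng(42)
    d, _ = _random_tree_distances(rng, 7)
    perm = rng.permutation(d.n_taxa)
    shuffled = DissimilarityMatrix(
        tuple(d.taxon_labels[i] for i in perm),
        d.values[np.ix_(perm, perm)],
        d.comparable_counts[np.ix_(perm, perm)],
    )
    t1 = neighbour_joining(d)
    t2 = neighbour_joining(shuffled)
    assert t1.compare_rfd(t2) == 0.0


def test_nj_newick_roundtrip_and_negative_clamp():
    d = _dm([[0, 0.9, 0.1, 0.9], [0.9, 0, 0.9, 0.1],
             [0.1, 0.9, 0, 0.85], [0.9, 0.1, 0.85, 0]])
    est = NeighborJoining().fit(d)
    reparsed = TreeNode.read(io.StringIO(est.newick_))
    got = reparsed.tip_tip_distances(endpoints=list(d.taxon_labels))
    orig = est.tree_.tip_tip_distances(endpoints=list(d.taxon_labels))
    assert np.allclose(np.asarray(got.data), np.asarray(orig.data), atol=1e-6)
    for node in est.tree_.traverse(include_self=False):
        assert node.length >= 0.0


# ----------------------------------------------------------------------
# k-means assessment
# ----------------------------------------------------------------------
def test_two_blobs_select_k2_with_high_silhouette():
    coords, _, _ = generate_point_clouds(2, 30, 2, centroid_separation=10.0,
                                         spread=1.0, seed=0)
    est = KMeansAssessment(k_range=(2, 5), random_state=0).fit(coords)
    assert est.best_k_ == 2
    assert est.scores_.loc[2, "silhouette"] > 0.7
    assert not est.weak_structure_


def test_single_blob_flags_weak_structure():
    coords, _, _ = generate_point_clouds(1, 60, 2, centroid_separation=0.0,
                                         spread=1.0, seed=1)
    est = KMeansAssessment(k_range=(2, 5), random_state=1).fit(coords)
    assert est.weak_structure_
    assert (est.scores_["silhouette"] < 0.5).all()


def test_duplicated_dataset_same_best_k():
    coords, _, _ = generate_point_clouds(3, 20, 2, centroid_separation=8.0,
                                         spread=1.0, seed=2)
    a = KMeansAssessment(k_range=(2, 5), random_state=3).fit(coords)
    b = KMeansAssessment(k_range=(2, 5), random_state=3).fit(
        np.vstack([coords, coords])
    )
    assert a.best_k_ == b.best_k_ == 3


def test_gap_criterion_on_separated_blobs():
    coords, _, _ = generate_point_clouds(2, 25, 2, centroid_separation=12.0,
                                         spread=1.0, seed=4)
    est = KMeansAssessment(k_range=(2, 5), criterion="gap",
                           random_state=5).fit(coords)
    assert est.best_k_ == 2
    assert {"gap", "gap_se"} <= set(est.scores_.columns)


def test_k_range_validation():
    coords = np.random.default_rng(6).standard_normal((10, 2))
    with pytest.raises(ValueError, match="must be <"):
        KMeansAssessment(k_range=(2, 10)).fit(coords)
    with pytest.raises(ValueError, match="start at"):
        KMeansAssessment(k_range=(1, 3)).fit(coords)
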