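"""KDE hypervolume estimation, overlap, inclusion and centroids."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from morphospace import (
    KDEHypervolume,
    TaxonGrouping,
    centroid_distances,
    estimate_hypervolume,
    group_centroids,
    pcoa,
    sorensen_overlap,
)
from morphospace.hypervolume import min_group_size


def test_unit_square_volume_close_to_one():
    """Analytic oracle: the area of the unit square is 1; a KDE with a
    small bandwidth and 5% quantile threshold should come close."""
    rng = np.random.default_rng(0)
    pts = rng.random((600, 2))
    hv = estimate_hypervolume(pts, bandwidth=0.05, threshold_quantile=0.05,
                              n_samples=40_000, seed=1)
    assert hv.volume_ == pytest.approx(1.0, rel=0.15)


@pytest.mark.parametrize("d", [1, 2])
def test_gaussian_contour_volume_closed_form(d):
    """The 95%-mass region of N(0, I_d) is a ball of radius
    sqrt(chi2.ppf(0.95, d)); the KDE estimate of many standard-normal
    points should approach its closed-form volume."""
    rng = np.random.default_rng(d)
    pts = rng.standard_normal((1500, d))
    hv = estimate_hypervolume(pts, threshold_quantile=0.05,
                              n_samples=60_000, seed=2)
    r = np.sqrt(chi2.ppf(0.95, d))
    analytic = 2 * r if d == 1 else np.pi * r**2
    assert hv.volume_ == pytest.approx(analytic, rel=0.15)


def test_volume_monotone_in_bandwidth_single_point():
    vols = [
        estimate_hypervolume(np.array([[0.0]]), bandwidth=h,
                             threshold_quantile=0.0, n_samples=5000,
                             seed=3).volume_
        for h in (0.1, 0.2, 0.4)
    ]
    assert vols[0] < vols[1] < vols[2]


def test_volume_additive_for_disjoint_clouds():
    rng = np.random.default_rng(4)
    a = rng.standard_normal((150, 2))
    b = rng.standard_normal((150, 2)) + [60.0, 0.0]
    joint = estimate_hypervolume(np.vstack([a, b]), bandwidth=1.0,
                                 threshold_quantile=0.05,
                                 n_samples=40_000, seed=5).volume_
    va = estimate_hypervolume(a, bandwidth=1.0, threshold_quantile=0.05,
                              n_samples=40_000, seed=6).volume_
    vb = estimate_hypervolume(b, bandwidth=1.0, threshold_quantile=0.05,
                              n_samples=40_000, seed=7).volume_
    assert joint == pytest.approx(va + vb, rel=0.2)


def test_volume_never_increases_with_threshold_quantile():
    rng = np.random.default_rng(8)
    pts = rng.standard_normal((100, 3))
    vols = [
        estimate_hypervolume(pts, threshold_quantile=q,
                             n_samples=20_000, seed=9).volume_
        for q in (0.01, 0.05, 0.1, 0.3)
    ]
    assert all(v1 >= v2 for v1, v2 in zip(vols, vols[1:]))


def test_consistency_identity_and_interior_points():
    rng = np.random.default_rng(10)
    pts = rng.standard_normal((200, 2))
    hv = estimate_hypervolume(pts, n_samples=20_000, seed=11)
    # stored uniform points all pass the model's own inclusion test
    assert hv.predict(hv.random_points_).all()
    assert hv.volume_ == pytest.approx(
        len(hv.random_points_) / hv.point_density_
    )
    assert hv.volume_ > 0


def test_inclusion_centroid_in_far_point_out():
    rng = np.random.default_rng(12)
    pts = rng.standard_normal((300, 3))
    hv = estimate_hypervolume(pts, n_samples=20_000, seed=13)
    assert hv.predict(pts.mean(axis=0, keepdims=True))[0]
    radius = np.linalg.norm(pts, axis=1).max()
    assert not hv.predict(np.full((1, 3), 10 * radius))[0]


def test_sorensen_self_overlap_and_disjoint():
    rng = np.random.default_rng(14)
    pts = rng.standard_normal((120, 2))
    a = estimate_hypervolume(pts, n_samples=30_000, seed=15)
    b = estimate_hypervolume(pts, n_samples=30_000, seed=16)
    self_overlap = sorensen_overlap(a, b)
    assert self_overlap.sorensen >= 0.9
    far = estimate_hypervolume(pts + 1000.0, n_samples=30_000, seed=17)
    assert sorensen_overlap(a, far).sorensen <= 0.05


def test_sorensen_symmetric_and_bounded():
    rng = np.random.default_rng(18)
    a = estimate_hypervolume(rng.standard_normal((80, 2)),
                             n_samples=20_000, seed=19)
    b = estimate_hypervolume(rng.standard_normal((80, 2)) + 1.0,
                             n_samples=20_000, seed=20)
    r1, r2 = sorensen_overlap(a, b), sorensen_overlap(b, a)
    assert r1.sorensen == pytest.approx(r2.sorensen)
    assert 0.0 <= r1.sorensen <= 1.0
    assert r1.intersection_volume <= min(a.volume_, b.volume_) + 1e-12


def test_dimension_and_bandwidth_errors():
    rng = np.random.default_rng(21)
    a = estimate_hypervolume(rng.standard_normal((50, 2)), n_samples=2000,
                             seed=22)
    b = estimate_hypervolume(rng.standard_normal((50, 3)), n_samples=2000,
                             seed=23)
    with pytest.raises(ValueError, match="dimension"):
        sorensen_overlap(a, b)
    with pytest.raises(ValueError, match="dimension"):
        a.predict(np.zeros((1, 3)))
    with pytest.raises(ValueError, match="bandwidth"):
        estimate_hypervolume(rng.standard_normal((50, 2)), bandwidth=0.0)
    with pytest.warns(UserWarning, match="n_samples"):
        estimate_hypervolume(rng.standard_normal((50, 2)), n_samples=150,
                             seed=24)


def test_min_group_size_rule():
    assert [min_group_size(d) for d in (1, 2, 3, 4)] == [3, 3, 4, 5]


def test_group_centroids_and_distances():
    from scipy.spatial.distance import pdist, squareform

    pts = np.array([[0.0, 0.0], [3.0, 4.0], [1.0, -1.0], [-1.0, 1.0]])
    ordination = pcoa(squareform(pdist(pts)))
    # PCoA coordinates preserve distances, so centroid distances computed
    # on them must match those computed from the raw coordinates
    grouping = TaxonGrouping({"0": "a", "1": "b", "2": "c", "3": "c"},
                             ("a", "b", "c"))
    cents = group_centroids(ordination, grouping,
                            n_axes=ordination.n_axes)
    dists = centroid_distances(cents)
    assert dists.loc["a", "b"] == pytest.approx(5.0)  # (0,0) vs (3,4)
    assert dists.loc["a", "c"] == pytest.approx(0.0, abs=1e-9)  # symmetric pair
    assert np.allclose(dists.values, dists.values.T)
    assert np.allclose(np.diag(dists.values), 0.0)


def test_centroid_distance_hand_example():
    cents = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["x", "y"])
    assert centroid_distances(cents).loc["x", "y"] == pytest.approx(5.0)
    with pytest.raises(ValueError):
        centroid_distances(cents.iloc[:1])
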