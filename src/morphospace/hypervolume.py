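"""Kernel-density hypervolumes of group point clouds in morphospace.

A group's hypervolume is the region of ordination space where a Gaussian
product-kernel density estimate of its points exceeds a threshold chosen
so that the region captures a fixed share (1 - ``threshold_quantile``) of
the mixture's probability mass. Its measure (the "volume") is estimated by
importance sampling from the kernel mixture itself:

    V = integral over {f >= c} dx = E_{x ~ f}[ 1{f(x) >= c} / f(x) ]

Uniformly distributed interior points are obtained by thinning the mixture
samples with acceptance probability ``c / f(x)``; these support the
Sorensen-Dice overlap (cross-inclusion of each model's uniform points in
the other model) and are what the classical morphospace "cloud" plots of
this method display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .matrix import TaxonGrouping
from .ordination import Ordination

__all__ = [
    "KDEHypervolume",
    "estimate_hypervolume",
    "OverlapResult",
    "sorensen_overlap",
    "overlap_table",
    "group_centroids",
    "centroid_distances",
    "min_group_size",
]


def min_group_size(dimension: int) -> int:
    """Smallest group for which a KDE hypervolume is attempted: 3 points
    up to two dimensions, ``dimension + 1`` above."""
    return 3 if dimension <= 2 else dimension + 1


class KDEHypervolume(BaseEstimator):
    """Kernel-density hypervolume of a point cloud.

    Parameters
    ----------
    bandwidth : "silverman", float, or array of shape (n_axes,)
        Per-axis Gaussian kernel bandwidth. ``"silverman"`` applies the
        multivariate Silverman rule per axis:
        ``h_j = sd_j * (4 / ((d + 2) n)) ** (1 / (d + 4))``.
    threshold_quantile : float in [0, 1), default=0.05
        Probability mass of the kernel mixture left *outside* the
        hypervolume; 0.05 keeps the densest region holding 95% of mass.
    n_samples : int, default=10000
        Monte-Carlo samples drawn from the mixture; controls the accuracy
        of both the threshold and the volume estimate.
    random_state : int or None

    Attributes
    ----------
    volume_ : float
    bandwidth_ : ndarray (per-axis bandwidths actually used)
    threshold_ : float (density threshold defining the region)
    random_points_ : ndarray, uniform interior points
    point_density_ : float, interior points per unit volume
    """

    def __init__(
        self,
        bandwidth="silverman",
        threshold_quantile: float = 0.05,
        n_samples: int = 10000,
        random_state: int | None = None,
    ):
        self.bandwidth = bandwidth
        self.threshold_quantile = threshold_quantile
        self.n_samples = n_samples
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X: np.ndarray, y=None) -> "KDEHypervolume":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n, d = X.shape
        if not 0.0 <= self.threshold_quantile < 1.0:
            raise ValueError("threshold_quantile must lie in [0, 1)")
        h = self._resolve_bandwidth(X)
        if np.any(h <= 0) or not np.all(np.isfinite(h)):
            raise ValueError(
                f"bandwidth must be positive and finite, got {h}; a zero "
                "Silverman bandwidth means an axis is constant"
            )
        if self.n_samples < 100 * d:
            import warnings

            warnings.warn(
                f"n_samples={self.n_samples} is small for dimension {d}; "
                "volume estimates will be noisy",
                stacklevel=2,
            )

        rng = np.random.default_rng(self.random_state)
        comp = rng.integers(0, n, size=self.n_samples)
        samples = X[comp] + rng.standard_normal((self.n_samples, d)) * h
        dens = _mixture_density(X, h, samples)
        threshold = (
            float(np.quantile(dens, self.threshold_quantile))
            if self.threshold_quantile > 0
            else float(dens.min())
        )
        inside = dens >= threshold
        with np.errstate(divide="ignore"):
            weights = np.where(inside, 1.0 / dens, 0.0)
        volume = float(weights.sum() / self.n_samples)

        # thin to uniform interior points: accept with prob c / f(x)
        accept = inside & (rng.random(self.n_samples) < threshold / dens)
        points = samples[accept]

        self.n_features_in_ = d
        self.data_points_ = X
        self.bandwidth_ = h
        self.threshold_ = threshold
        self.volume_ = volume
        self.random_points_ = points
        self.point_density_ = len(points) / volume if volume > 0 else np.inf
        return self

    def _resolve_bandwidth(self, X: np.ndarray) -> np.ndarray:
        n, d = X.shape
        if isinstance(self.bandwidth, str):
            if self.bandwidth != "silverman":
                raise ValueError(f"unknown bandwidth rule {self.bandwidth!r}")
            if n < 2:
                raise ValueError(
                    "Silverman bandwidth needs >= 2 points; pass an "
                    "explicit bandwidth for a single point"
                )
            sd = X.std(axis=0, ddof=1)
            return sd * (4.0 / ((d + 2.0) * n)) ** (1.0 / (d + 4.0))
        h = np.asarray(self.bandwidth, dtype=float)
        return np.full(d, float(h)) if h.ndim == 0 else h

    # ------------------------------------------------------------------
    def score_samples(self, X: np.ndarray) -> np.ndarray:
        """Kernel mixture density at query points."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"query dimension {X.shape[1]} != model dimension "
                f"{self.n_features_in_}"
            )
        return _mixture_density(self.data_points_, self.bandwidth_, X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Inclusion test: True where the fitted density exceeds the
        model's threshold."""
        return self.score_samples(X) >= self.threshold_


def estimate_hypervolume(
    points: np.ndarray,
    bandwidth="silverman",
    threshold_quantile: float = 0.05,
    n_samples: int = 10000,
    seed: int | None = None,
) -> KDEHypervolume:
    """Functional wrapper returning a fitted :class:`KDEHypervolume`."""
    return KDEHypervolume(
        bandwidth=bandwidth,
        threshold_quantile=threshold_quantile,
        n_samples=n_samples,
        random_state=seed,
    ).fit(points)


def _mixture_density(
    data: np.ndarray, h: np.ndarray, query: np.ndarray
) -> np.ndarray:
    """Gaussian product-kernel mixture density, chunked over queries."""
    n, d = data.shape
    norm = 1.0 / (n * np.prod(np.sqrt(2.0 * np.pi) * h))
    out = np.empty(len(query))
    chunk = max(1, int(4_000_000 / max(n * d, 1)))
    for start in range(0, len(query), chunk):
        q = query[start : start + chunk]
        z = (q[:, None, :] - data[None, :, :]) / h
        out[start : start + chunk] = norm * np.exp(
            -0.5 * (z**2).sum(axis=2)
        ).sum(axis=1)
    return out


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class OverlapResult:
    """Sorensen-Dice overlap between two hypervolumes."""

    label_a: str
    label_b: str
    volume_a: float
    volume_b: float
    intersection_volume: float
    union_volume: float
    sorensen: float


def sorensen_overlap(
    A: KDEHypervolume,
    B: KDEHypervolume,
    label_a: str = "A",
    label_b: str = "B",
) -> OverlapResult:
    """Overlap of two fitted hypervolumes.

    The intersection volume is estimated symmetrically by cross-inclusion:
    the fraction of A's uniform interior points that fall inside B scales
    V(A), and vice versa, and the two estimates are averaged. Sorensen is
    ``2 V(A & B) / (V(A) + V(B))``.
    """
    if A.n_features_in_ != B.n_features_in_:
        raise ValueError(
            f"dimension mismatch: {A.n_features_in_} vs {B.n_features_in_}"
        )
    va, vb = A.volume_, B.volume_
    if va <= 0 or vb <= 0:
        raise ValueError("both hypervolumes must have positive volume")
    frac_a_in_b = float(np.mean(B.predict(A.random_points_))) if len(
        A.random_points_
    ) else 0.0
    frac_b_in_a = float(np.mean(A.predict(B.random_points_))) if len(
        B.random_points_
    ) else 0.0
    inter = 0.5 * (frac_a_in_b * va + frac_b_in_a * vb)
    inter = min(inter, va, vb)
    union = va + vb - inter
    sorensen = float(np.clip(2.0 * inter / (va + vb), 0.0, 1.0))
    return OverlapResult(label_a, label_b, va, vb, inter, union, sorensen)


def overlap_table(models: dict[str, KDEHypervolume]) -> pd.DataFrame:
    """Pairwise overlap summary for a dict of fitted models."""
    rows = []
    labels = list(models)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            r = sorensen_overlap(models[a], models[b], a, b)
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "volume_a": r.volume_a,
                    "volume_b": r.volume_b,
                    "intersection": r.intersection_volume,
                    "union": r.union_volume,
                    "sorensen": r.sorensen,
                }
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
def group_centroids(
    ordination: Ordination,
    grouping: TaxonGrouping,
    n_axes: int | None = None,
    models: dict[str, KDEHypervolume] | None = None,
) -> pd.DataFrame:
    """Group centroids on the retained ordination axes.

    By default the centroid is the arithmetic mean of the member taxa's
    coordinates. If ``models`` is given, the mean of each group's
    hypervolume interior points is used instead.
    """
    if models is not None:
        rows = {g: m.random_points_.mean(axis=0) for g, m in models.items()}
        d = next(iter(models.values())).n_features_in_
    else:
        coords = ordination.retained_coordinates(n_axes)
        taxa = list(ordination.taxon_labels)
        d = coords.shape[1]
        rows = {}
        for g in grouping.groups_of_interest:
            members = grouping.members(g)
            if not members:
                raise ValueError(f"group {g!r} has no members")
            idx = [taxa.index(t) for t in members]
            rows[g] = coords[idx].mean(axis=0)
    cols = [f"axis{i + 1}" for i in range(d)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def centroid_distances(centroids: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between group centroids."""
    if centroids.shape[0] < 2:
        raise ValueError("need at least two centroids")
    from scipy.spatial.distance import pdist

    dist = squareform(pdist(centroids.to_numpy()))
    return pd.DataFrame(dist, index=centroids.index, columns=centroids.index)
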