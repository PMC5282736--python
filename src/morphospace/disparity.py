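"""Group disparity on ordination axes: sums of ranges/variances with
jackknife rarefaction and permutation tests.

The observed sum of ranges grows with sample size, so groups of unequal
size are compared after rarefying: each group is repeatedly subsampled
without replacement to a common size (default: the smallest group of
interest) and the metric recomputed, giving a jackknife distribution per
group. Pairwise differences are tested by permutation: the two groups'
taxa are pooled and randomly re-partitioned into the observed group sizes,
and the p-value is the +1-corrected fraction of null absolute differences
at least as large as the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .matrix import TaxonGrouping
from .ordination import Ordination

__all__ = [
    "sum_of_ranges",
    "sum_of_variances",
    "DisparityResult",
    "DisparityResampler",
    "jackknife_disparity",
    "permutation_test",
]


def sum_of_ranges(points: np.ndarray) -> float:
    """Sum over axes of (max - min) of the coordinates.

    Ignores point multiplicity; zero for a single point.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 1 or pts.size == 0:
        raise ValueError("sum_of_ranges needs at least one point")
    return float((pts.max(axis=0) - pts.min(axis=0)).sum())


def sum_of_variances(points: np.ndarray) -> float:
    """Sum over axes of the sample variance (n-1 denominator)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 2:
        raise ValueError("sum_of_variances needs at least two points")
    return float(pts.var(axis=0, ddof=1).sum())


_METRICS = {"sum_of_ranges": sum_of_ranges, "sum_of_variances": sum_of_variances}


@dataclass
class DisparityResult:
    """Observed and resampled disparity per group."""

    metric: str
    observed: dict[str, float]
    replicates: dict[str, np.ndarray]
    pairwise_p: pd.DataFrame
    iterations: int
    subsample_size: int
    seed: int | None = None
    summary: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.summary is None:
            rows = {}
            for g, reps in self.replicates.items():
                rows[g] = {
                    "observed": self.observed[g],
                    "jackknife_mean": float(np.mean(reps)),
                    "q025": float(np.quantile(reps, 0.025)),
                    "q975": float(np.quantile(reps, 0.975)),
                }
            self.summary = pd.DataFrame.from_dict(rows, orient="index")

    def replicate_table(self) -> pd.DataFrame:
        """Long-format (group, iteration, value) replicate table."""
        frames = [
            pd.DataFrame(
                {
                    "group": g,
                    "iteration": np.arange(len(reps)),
                    "value": reps,
                }
            )
            for g, reps in self.replicates.items()
        ]
        return pd.concat(frames, ignore_index=True)


class DisparityResampler(BaseEstimator):
    """Jackknifed disparity with pairwise permutation tests.

    Parameters
    ----------
    metric : {"sum_of_ranges", "sum_of_variances"}
    n_iterations : int, default=5000
        Jackknife replicates per group and permutations per pair.
    subsample_size : int or None
        Taxa drawn (without replacement) per jackknife replicate; ``None``
        rarefies every group to the smallest group's size.
    random_state : int or None

    Attributes
    ----------
    result_ : DisparityResult
    """

    def __init__(
        self,
        metric: str = "sum_of_ranges",
        n_iterations: int = 5000,
        subsample_size: int | None = None,
        random_state: int | None = None,
    ):
        self.metric = metric
        self.n_iterations = n_iterations
        self.subsample_size = subsample_size
        self.random_state = random_state

    def fit(self, X: np.ndarray, y) -> "DisparityResampler":
        """Resample disparity of groups ``y`` over coordinates ``X``.

        ``X`` is (n_taxa, n_axes); ``y`` is a group label per row. Every
        distinct label with >= 2 members is analysed.
        """
        if self.metric not in _METRICS:
            raise ValueError(f"metric must be one of {sorted(_METRICS)}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        if len(y) != X.shape[0]:
            raise ValueError("label length does not match coordinate rows")
        metric_fn = _METRICS[self.metric]
        groups = [g for g in dict.fromkeys(y.tolist())]
        idx_by_group = {g: np.flatnonzero(y == g) for g in groups}
        small = [g for g in groups if len(idx_by_group[g]) < 2]
        if small:
            raise ValueError(f"groups with < 2 members: {small}")

        size = self.subsample_size
        if size is None:
            size = min(len(v) for v in idx_by_group.values())
        if size < 2:
            raise ValueError("subsample_size must be >= 2")
        for g, idx in idx_by_group.items():
            if size > len(idx):
                raise ValueError(
                    f"subsample_size {size} exceeds size of group {g!r} "
                    f"({len(idx)} taxa)"
                )

        rng = np.random.default_rng(self.random_state)
        observed = {g: metric_fn(X[idx]) for g, idx in idx_by_group.items()}
        replicates = {
            g: _jackknife(X, idx, metric_fn, self.n_iterations, size, rng)
            for g, idx in idx_by_group.items()
        }
        pvals = pd.DataFrame(np.ones((len(groups), len(groups))),
                             index=groups, columns=groups)
        for a_i in range(len(groups)):
            for b_i in range(a_i + 1, len(groups)):
                a, b = groups[a_i], groups[b_i]
                p = _permutation_p(
                    X, idx_by_group[a], idx_by_group[b], metric_fn,
                    self.n_iterations, rng,
                )
                pvals.loc[a, b] = pvals.loc[b, a] = p

        self.result_ = DisparityResult(
            metric=self.metric,
            observed=observed,
            replicates=replicates,
            pairwise_p=pvals,
            iterations=self.n_iterations,
            subsample_size=size,
            seed=self.random_state,
        )
        return self


def _jackknife(X, idx, metric_fn, iterations, size, rng) -> np.ndarray:
    if size == len(idx):
        value = metric_fn(X[idx])
        return np.full(iterations, value)
    # random subsets without replacement via argsort of uniforms
    order = np.argsort(rng.random((iterations, len(idx))), axis=1)[:, :size]
    sub = X[idx[order]]  # iterations x size x axes
    return _metric_batch(sub, metric_fn)


def _metric_batch(batch: np.ndarray, metric_fn) -> np.ndarray:
    if metric_fn is sum_of_ranges:
        return (batch.max(axis=1) - batch.min(axis=1)).sum(axis=1)
    if metric_fn is sum_of_variances:
        return batch.var(axis=1, ddof=1).sum(axis=1)
    return np.array([metric_fn(b) for b in batch])


def _permutation_p(X, idx_a, idx_b, metric_fn, iterations, rng) -> float:
    observed = abs(metric_fn(X[idx_a]) - metric_fn(X[idx_b]))
    pool = np.concatenate([idx_a, idx_b])
    na = len(idx_a)
    order = np.argsort(rng.random((iterations, len(pool))), axis=1)
    perm = pool[order]
    stat_a = _metric_batch(X[perm[:, :na]], metric_fn)
    stat_b = _metric_batch(X[perm[:, na:]], metric_fn)
    null = np.abs(stat_a - stat_b)
    return float((np.sum(null >= observed - 1e-12) + 1) / (iterations + 1))


# ----------------------------------------------------------------------
def _coords_and_labels(
    ordination: Ordination, grouping: TaxonGrouping, n_axes: int | None
):
    coords = ordination.retained_coordinates(n_axes)
    taxa = list(ordination.taxon_labels)
    keep, labels = [], []
    for g in grouping.groups_of_interest:
        for t in grouping.members(g):
            if t not in taxa:
                raise ValueError(f"grouped taxon {t!r} absent from ordination")
            keep.append(taxa.index(t))
            labels.append(g)
    return coords[keep], np.array(labels)


def jackknife_disparity(
    ordination: Ordination,
    grouping: TaxonGrouping,
    metric: str = "sum_of_ranges",
    iterations: int = 5000,
    subsample_size: int | None = None,
    seed: int | None = None,
    n_axes: int | None = None,
) -> DisparityResult:
    """Jackknifed disparity of the groups of interest on retained axes."""
    X, y = _coords_and_labels(ordination, grouping, n_axes)
    est = DisparityResampler(metric, iterations, subsample_size, seed).fit(X, y)
    return est.result_


def permutation_test(
    ordination: Ordination,
    grouping: TaxonGrouping,
    metric: str = "sum_of_ranges",
    iterations: int = 5000,
    seed: int | None = None,
    n_axes: int | None = None,
) -> pd.DataFrame:
    """Pairwise permutation p-values for group disparity differences."""
    X, y = _coords_and_labels(ordination, grouping, n_axes)
    metric_fn = _METRICS[metric]
    rng = np.random.default_rng(seed)
    groups = list(dict.fromkeys(y.tolist()))
    pvals = pd.DataFrame(np.ones((len(groups),) * 2), index=groups, columns=groups)
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            p = _permutation_p(
                X, np.flatnonzero(y == a), np.flatnonzero(y == b),
                metric_fn, iterations, rng,
            )
            pvals.loc[a, b] = pvals.loc[b, a] = p
    return pvals
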