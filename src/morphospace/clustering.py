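"""Phenetic clustering: neighbour-joining phenograms and k-means
cluster-number assessment.

Neighbour joining follows Saitou & Nei's agglomeration: the pair
minimising the Q-criterion is joined, two-point formulas give the new
branch lengths, and the distance matrix is reduced until the three-taxon
closure. Gower-type matrices are not additive, so negative branch-length
estimates can occur; they are clamped to zero with the excess transferred
to the sister branch (preserving the joined pair's path length), and each
such event is recorded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import TreeNode
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .dissimilarity import DissimilarityMatrix

__all__ = [
    "deduplicate",
    "NeighborJoining",
    "neighbour_joining",
    "KMeansAssessment",
    "kmeans_assessment",
]


# ----------------------------------------------------------------------
def deduplicate(
    D: DissimilarityMatrix, tolerance: float = 0.0
) -> tuple[DissimilarityMatrix, dict[str, list[str]]]:
    """Merge taxa whose pairwise distance is at most ``tolerance``.

    Members at distance <= tolerance (transitively) collapse to a single
    representative (the first member in input order); its distance to any
    other taxon is the mean over member distances ("branch lengths
    averaged"). Returns the reduced matrix and a map
    representative -> members (singletons included). Idempotent.
    """
    D.require_complete()
    n = D.n_taxa
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if D.values[i, j] <= tolerance:
                parent[find(j)] = find(i)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    reps = sorted(clusters, key=lambda r: min(clusters[r]))
    labels = tuple(D.taxon_labels[min(clusters[r])] for r in reps)
    k = len(reps)
    values = np.zeros((k, k))
    counts = np.zeros((k, k), dtype=int)
    for a in range(k):
        for b in range(a + 1, k):
            ia, ib = clusters[reps[a]], clusters[reps[b]]
            block = D.values[np.ix_(ia, ib)]
            values[a, b] = values[b, a] = float(block.mean())
            counts[a, b] = counts[b, a] = int(
                D.comparable_counts[np.ix_(ia, ib)].mean()
            )
    merges = {
        D.taxon_labels[min(clusters[r])]: [D.taxon_labels[i] for i in clusters[r]]
        for r in reps
    }
    reduced = DissimilarityMatrix(
        labels, values, counts, D.method, D.polymorphism_rule
    )
    return reduced, merges


# ----------------------------------------------------------------------
class NeighborJoining(BaseEstimator):
    """Saitou-Nei neighbour joining of a dissimilarity matrix.

    Ties in the Q-criterion break to the lowest (row, column) index pair,
    making the agglomeration deterministic.

    Attributes
    ----------
    tree_ : skbio.TreeNode
        Unrooted tree (the root is a degree-3 internal node).
    newick_ : str
    negative_branch_events_ : int
        Count of negative branch-length estimates clamped to zero.
    """

    def fit(self, D: DissimilarityMatrix | np.ndarray, y=None) -> "NeighborJoining":
        if isinstance(D, DissimilarityMatrix):
            D.require_complete()
            labels = list(D.taxon_labels)
            dist = D.values.copy()
        else:
            dist = np.asarray(D, dtype=float).copy()
            labels = [str(i) for i in range(dist.shape[0])]
        if dist.shape[0] < 3:
            raise ValueError("neighbour joining needs at least 3 taxa")
        if np.isnan(dist).any():
            raise ValueError("distance matrix contains undefined entries")

        nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
        clamped = 0

        while len(nodes) > 3:
            m = len(nodes)
            r = dist.sum(axis=1)
            q = (m - 2) * dist - r[:, None] - r[None, :]
            np.fill_diagonal(q, np.inf)
            # row-major argmin gives the lowest (i, j) among ties
            i, j = np.unravel_index(np.argmin(q), q.shape)
            if i > j:
                i, j = j, i
            dij = dist[i, j]
            li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
            lj = dij - li
            li, lj, n_cl = _clamp_pair(li, lj)
            clamped += n_cl
            child_i, child_j = nodes[i], nodes[j]
            child_i.length = li
            child_j.length = lj
            new = TreeNode(children=[child_i, child_j])
            new_dist = 0.5 * (dist[i, :] + dist[j, :] - dij)
            keep = [x for x in range(m) if x not in (i, j)]
            reduced = dist[np.ix_(keep, keep)]
            dist = np.zeros((len(keep) + 1, len(keep) + 1))
            dist[:-1, :-1] = reduced
            dist[-1, :-1] = dist[:-1, -1] = new_dist[keep]
            nodes = [nodes[x] for x in keep] + [new]

        # three-taxon closure
        d01, d02, d12 = dist[0, 1], dist[0, 2], dist[1, 2]
        lengths = [
            0.5 * (d01 + d02 - d12),
            0.5 * (d01 + d12 - d02),
            0.5 * (d02 + d12 - d01),
        ]
        for node, length in zip(nodes, lengths):
            if length < 0:
                clamped += 1
                length = 0.0
            node.length = float(length)
        root = TreeNode(children=nodes)

        self.tree_ = root
        self.newick_ = str(root).strip()
        self.negative_branch_events_ = clamped
        return self


def _clamp_pair(li: float, lj: float) -> tuple[float, float, int]:
    """Clamp a negative branch estimate to zero, moving the excess to the
    sister branch so the joined pair's path length is preserved."""
    clamped = 0
    if li < 0:
        lj += li
        li = 0.0
        clamped += 1
    if lj < 0:
        li += lj
        lj = 0.0
        clamped += 1
    return float(max(li, 0.0)), float(max(lj, 0.0)), clamped


def neighbour_joining(D: DissimilarityMatrix | np.ndarray) -> TreeNode:
    """Functional wrapper returning the NJ tree."""
    return NeighborJoining().fit(D).tree_


# ----------------------------------------------------------------------
class KMeansAssessment(BaseEstimator):
    """Assess the number of k-means clusters on ordination coordinates.

    Parameters
    ----------
    k_range : (int, int), default=(2, 6)
        Inclusive range of cluster counts to score.
    criterion : {"silhouette", "gap"}, default="silhouette"
        "silhouette": best k maximises the mean silhouette width.
        "gap": Tibshirani's gap statistic against uniform bounding-box
        references; best k is the smallest k with
        ``gap(k) >= gap(k+1) - s(k+1)``.
    n_restarts : int, default=10
        k-means restarts per k (best inertia kept).
    n_references : int, default=10
        Reference datasets for the gap statistic.
    random_state : int or None

    Attributes
    ----------
    scores_ : DataFrame indexed by k with inertia and criterion score
    best_k_ : int
    labels_ : ndarray, cluster labels at best_k_
    weak_structure_ : bool
        True when the best silhouette is below 0.5, flagging the absence
        of strong cluster structure (Kaufman-Rousseeuw reading).
    """

    def __init__(
        self,
        k_range: tuple[int, int] = (2, 6),
        criterion: str = "silhouette",
        n_restarts: int = 10,
        n_references: int = 10,
        random_state: int | None = None,
    ):
        self.k_range = k_range
        self.criterion = criterion
        self.n_restarts = n_restarts
        self.n_references = n_references
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None) -> "KMeansAssessment":
        if self.criterion not in ("silhouette", "gap"):
            raise ValueError("criterion must be 'silhouette' or 'gap'")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = X.shape[0]
        lo, hi = int(self.k_range[0]), int(self.k_range[1])
        if lo < 2:
            raise ValueError("k_range must start at >= 2")
        if hi >= n:
            raise ValueError(f"k_range upper bound {hi} must be < n = {n}")
        rng = np.random.default_rng(self.random_state)

        ks = list(range(lo, hi + 1))
        rows, all_labels = [], {}
        for k in ks:
            km = KMeans(
                n_clusters=k,
                n_init=self.n_restarts,
                random_state=int(rng.integers(2**31)),
            ).fit(X)
            sil = float(silhouette_score(X, km.labels_))
            row = {"k": k, "inertia": float(km.inertia_), "silhouette": sil}
            if self.criterion == "gap":
                gap, s = _gap_statistic(
                    X, k, self.n_restarts, self.n_references, rng
                )
                row["gap"] = gap
                row["gap_se"] = s
            rows.append(row)
            all_labels[k] = km.labels_

        scores = pd.DataFrame(rows).set_index("k")
        if self.criterion == "silhouette":
            best_k = int(scores["silhouette"].idxmax())
        else:
            best_k = ks[-1]
            for idx, k in enumerate(ks[:-1]):
                nxt = ks[idx + 1]
                if scores.loc[k, "gap"] >= (
                    scores.loc[nxt, "gap"] - scores.loc[nxt, "gap_se"]
                ):
                    best_k = k
                    break

        self.scores_ = scores
        self.best_k_ = best_k
        self.labels_ = all_labels[best_k]
        self.weak_structure_ = bool(scores["silhouette"].max() < 0.5)
        return self


def _gap_statistic(X, k, n_restarts, n_refs, rng):
    def log_wk(data):
        km = KMeans(
            n_clusters=k, n_init=n_restarts,
            random_state=int(rng.integers(2**31)),
        ).fit(data)
        return np.log(max(km.inertia_, np.finfo(float).tiny))

    lo, hi = X.min(axis=0), X.max(axis=0)
    ref_logs = np.array(
        [
            log_wk(rng.uniform(lo, hi, size=X.shape))
            for _ in range(n_refs)
        ]
    )
    gap = float(ref_logs.mean() - log_wk(X))
    s = float(ref_logs.std(ddof=0) * np.sqrt(1.0 + 1.0 / n_refs))
    return gap, s


def kmeans_assessment(
    X: np.ndarray,
    k_range: tuple[int, int] = (2, 6),
    criterion: str = "silhouette",
    n_restarts: int = 10,
    seed: int | None = None,
) -> KMeansAssessment:
    """Functional wrapper returning a fitted :class:`KMeansAssessment`."""
    return KMeansAssessment(
        k_range=k_range,
        criterion=criterion,
        n_restarts=n_restarts,
        random_state=seed,
    ).fit(X)
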