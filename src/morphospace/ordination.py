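"""Principal coordinates analysis (metric MDS) of a dissimilarity matrix.

PCoA eigendecomposes the Gower-centred matrix of ``-D**2 / 2``. Coordinates
are eigenvectors scaled by the square root of their eigenvalues, so
Euclidean distances between taxa in the full configuration reproduce the
input distances whenever those are Euclidean-embeddable. Non-Euclidean
inputs (the usual case for Gower/MORD matrices) produce negative
eigenvalues, handled either by dropping them with a warning (default) or
by the Lingoes / Cailliez additive-constant corrections.

The number of "significant" axes is chosen against the Broken-Stick null:
axis k is retained while its relative eigenvalue exceeds the expectation
``b_k = (1/p) * sum_{i=k..p} 1/i``, stopping at the first failure, with a
floor of one axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .dissimilarity import DissimilarityMatrix

__all__ = [
    "Ordination",
    "PCoA",
    "pcoa",
    "broken_stick_expectation",
    "retained_axes",
]

_CORRECTIONS = ("none", "lingoes", "cailliez")


@dataclass(frozen=True)
class Ordination:
    """PCoA configuration: coordinates on positive-eigenvalue axes."""

    taxon_labels: tuple[str, ...]
    coordinates: np.ndarray  # taxa x axes, axes ordered by eigenvalue
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    relative_eigenvalues: np.ndarray  # positive eigenvalues / their sum
    correction: str
    correction_constant: float
    n_retained: int

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def retained_coordinates(self, n: int | None = None) -> np.ndarray:
        """Coordinates restricted to the first ``n`` (default retained) axes."""
        k = self.n_retained if n is None else n
        return self.coordinates[:, :k]

    def to_dataframe(self, n: int | None = None) -> pd.DataFrame:
        coords = self.coordinates if n is None else self.coordinates[:, :n]
        cols = [f"axis{i + 1}" for i in range(coords.shape[1])]
        return pd.DataFrame(coords, index=list(self.taxon_labels), columns=cols)

    def eigenvalue_table(self) -> pd.DataFrame:
        p = len(self.relative_eigenvalues)
        table = pd.DataFrame(
            {
                "eigenvalue": self.eigenvalues,
                "relative": np.concatenate(
                    [self.relative_eigenvalues,
                     np.full(len(self.eigenvalues) - p, np.nan)]
                ),
            }
        )
        table["broken_stick"] = np.concatenate(
            [broken_stick_expectation(p),
             np.full(len(self.eigenvalues) - p, np.nan)]
        )
        table.index = [f"axis{i + 1}" for i in range(len(table))]
        return table


class PCoA(BaseEstimator):
    """Principal coordinates analysis estimator.

    Parameters
    ----------
    correction : {"none", "lingoes", "cailliez"}, default="none"
        Treatment of negative eigenvalues. ``"none"`` drops them with a
        warning; the other two apply the corresponding additive constant
        to the off-diagonal distances and re-decompose.

    Attributes
    ----------
    ordination_ : Ordination
    coordinates_ : ndarray of shape (n_taxa, n_positive_axes)
    eigenvalues_ : ndarray, non-increasing, including negatives
    n_retained_ : int, Broken-Stick significant axis count
    """

    def __init__(self, correction: str = "none"):
        self.correction = correction

    def fit(self, D: DissimilarityMatrix | np.ndarray, y=None) -> "PCoA":
        if self.correction not in _CORRECTIONS:
            raise ValueError(f"correction must be one of {_CORRECTIONS}")
        if isinstance(D, DissimilarityMatrix):
            D.require_complete()
            labels = D.taxon_labels
            dist = D.values
        else:
            dist = np.asarray(D, dtype=float)
            labels = tuple(str(i) for i in range(dist.shape[0]))
        _validate_distances(dist)

        constant = 0.0
        eigval, eigvec = _decompose(dist)
        if self.correction != "none" and eigval.min() < -_tol(eigval):
            if self.correction == "lingoes":
                constant = float(-eigval.min())
                d2 = dist**2 + 2.0 * constant
                np.fill_diagonal(d2, 0.0)
                corrected = np.sqrt(d2)
            else:  # cailliez
                constant = _cailliez_constant(dist)
                corrected = dist + constant
                np.fill_diagonal(corrected, 0.0)
            eigval, eigvec = _decompose(corrected)

        tol = _tol(eigval)
        pos = eigval > tol
        n_pos = int(pos.sum())
        if self.correction == "none" and (eigval < -tol).any():
            neg_share = -eigval[eigval < -tol].sum() / max(
                eigval[pos].sum(), np.finfo(float).tiny
            )
            warnings.warn(
                f"{int((eigval < -tol).sum())} negative eigenvalue(s) "
                f"dropped ({neg_share:.1%} of positive mass); consider a "
                "lingoes or cailliez correction",
                stacklevel=2,
            )

        if n_pos == 0:
            coords = np.zeros((dist.shape[0], 1))
            rel = np.array([1.0])
            n_retained = 1
        else:
            coords = eigvec[:, :n_pos] * np.sqrt(eigval[:n_pos])
            coords = _fix_signs(coords)
            rel = eigval[:n_pos] / eigval[:n_pos].sum()
            n_retained = retained_axes(rel)

        self.ordination_ = Ordination(
            taxon_labels=tuple(labels),
            coordinates=coords,
            eigenvalues=eigval,
            relative_eigenvalues=rel,
            correction=self.correction,
            correction_constant=constant,
            n_retained=n_retained,
        )
        self.coordinates_ = coords
        self.eigenvalues_ = eigval
        self.relative_eigenvalues_ = rel
        self.n_retained_ = n_retained
        return self

    def fit_transform(self, D, y=None) -> np.ndarray:
        return self.fit(D).coordinates_


def pcoa(D: DissimilarityMatrix | np.ndarray, correction: str = "none") -> Ordination:
    """Functional wrapper: fit :class:`PCoA` and return the ordination."""
    return PCoA(correction=correction).fit(D).ordination_


# ----------------------------------------------------------------------
def _validate_distances(dist: np.ndarray) -> None:
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(dist).any():
        raise ValueError("distance matrix contains undefined entries")
    if not np.allclose(dist, dist.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    if (dist < -1e-12).any():
        raise ValueError("distances must be non-negative")


def _decompose(dist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = dist.shape[0]
    a = -0.5 * dist**2
    row = a.mean(axis=1, keepdims=True)
    b = a - row - row.T + a.mean()
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    return eigval[order], eigvec[:, order]


def _tol(eigval: np.ndarray) -> float:
    scale = max(abs(eigval).max(), 1.0)
    return 1e-10 * scale


def _cailliez_constant(dist: np.ndarray) -> float:
    n = dist.shape[0]
    h = np.eye(n) - np.full((n, n), 1.0 / n)
    d1 = h @ (-0.5 * dist**2) @ h
    d2 = h @ (-0.5 * dist) @ h
    special = np.block(
        [[np.zeros((n, n)), 2.0 * d1], [-np.eye(n), -4.0 * d2]]
    )
    eig = np.linalg.eigvals(special)
    return float(np.max(eig.real))


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude loading on each axis positive."""
    idx = np.argmax(np.abs(coords), axis=0)
    signs = np.sign(coords[idx, np.arange(coords.shape[1])])
    signs[signs == 0] = 1.0
    return coords * signs


# ----------------------------------------------------------------------
def broken_stick_expectation(p: int) -> np.ndarray:
    """Broken-Stick proportions ``b_k = (1/p) * sum_{i=k..p} 1/i``."""
    if p < 1:
        raise ValueError("p must be >= 1")
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def retained_axes(relative_eigenvalues: np.ndarray) -> int:
    """Leading axes whose relative eigenvalue exceeds the Broken-Stick
    expectation, stopping at the first failure; at least 1."""
    rel = np.asarray(relative_eigenvalues, dtype=float)
    if rel.size == 0:
        raise ValueError("need at least one positive eigenvalue")
    expected = broken_stick_expectation(rel.size)
    n = 0
    for r, e in zip(rel, expected):
        if r > e:
            n += 1
        else:
            break
    return max(n, 1)
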