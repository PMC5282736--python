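"""Pairwise taxon dissimilarities under pairwise deletion.

Distances are computed over the characters scored in *both* taxa of a pair
(missing and inapplicable cells are deleted pairwise; inapplicable is
treated as uncertainty, exactly like missing). Three indices are offered:

``gower``
    Mean per-character difference, where the difference is a 0/1 mismatch
    for unordered characters and ``|a - b| / range`` for ordered ones.
``mord``
    Maximum observable rescaled distance: the sum of raw per-character
    differences divided by the sum of the maximum attainable differences
    over the comparable characters. Coincides with Gower when every
    comparable character is unordered.
``hamming``
    Raw mismatch proportion (any difference counts 1).

Polymorphic cells are resolved by a configurable rule: ``"min"`` takes the
smallest difference achievable by any pair of states (distance 0 when the
state sets intersect), ``"mean"`` averages over all state pairs.

Gower-type distances under pairwise deletion need not satisfy the triangle
inequality; no such guarantee is made here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .matrix import CharacterMatrix

__all__ = [
    "DissimilarityMatrix",
    "CategoricalDissimilarity",
    "pairwise_dissimilarity",
    "distance_completeness_report",
    "UndefinedDistanceError",
]

_METHODS = ("gower", "mord", "hamming")
_POLY_RULES = ("min", "mean")


class UndefinedDistanceError(ValueError):
    """A taxon pair shares no scored characters."""


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric pairwise taxon dissimilarities.

    ``values`` holds NaN for undefined pairs (no comparable characters);
    ``comparable_counts[i, j]`` is the number of characters scored in both
    taxa ``i`` and ``j``.
    """

    taxon_labels: tuple[str, ...]
    values: np.ndarray
    comparable_counts: np.ndarray
    method: str = "mord"
    polymorphism_rule: str = "min"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        n = len(self.taxon_labels)
        if values.shape != (n, n):
            raise ValueError("values shape does not match taxon count")
        if not np.allclose(np.diag(values), 0.0):
            raise ValueError("diagonal must be zero")
        finite = ~np.isnan(values)
        if not np.allclose(
            values[finite & finite.T], values.T[finite & finite.T]
        ):
            raise ValueError("values must be symmetric")
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self,
            "comparable_counts",
            np.asarray(self.comparable_counts, dtype=int),
        )

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_labels)

    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        nan = np.isnan(self.values)
        for i in range(self.n_taxa):
            for j in range(i + 1, self.n_taxa):
                if nan[i, j]:
                    out.append((self.taxon_labels[i], self.taxon_labels[j]))
        return out

    def require_complete(self) -> None:
        bad = self.undefined_pairs()
        if bad:
            raise UndefinedDistanceError(
                f"{len(bad)} taxon pair(s) share no scored characters: "
                f"{bad[:5]}{'...' if len(bad) > 5 else ''}"
            )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.taxon_labels, columns=self.taxon_labels
        )

    def to_skbio(self):
        from skbio import DistanceMatrix

        self.require_complete()
        return DistanceMatrix(self.values, ids=list(self.taxon_labels))

    def condensed(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        self.require_complete()
        return squareform(self.values, checks=False)

    def subset(self, keep: Sequence[str]) -> "DissimilarityMatrix":
        idx = [self.taxon_labels.index(t) for t in keep]
        return DissimilarityMatrix(
            tuple(self.taxon_labels[i] for i in idx),
            self.values[np.ix_(idx, idx)],
            self.comparable_counts[np.ix_(idx, idx)],
            self.method,
            self.polymorphism_rule,
        )

    # -- exports ------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "taxon"
        df.to_csv(path, float_format="%.6g")

    def to_phylip(self, path: str | Path) -> None:
        """Lower-triangle PHYLIP-style distance text."""
        lines = [str(self.n_taxa)]
        for i, label in enumerate(self.taxon_labels):
            row = " ".join(f"{self.values[i, j]:.6f}" for j in range(i))
            lines.append(f"{label.replace(' ', '_'):<12} {row}".rstrip())
        Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
class CategoricalDissimilarity(BaseEstimator):
    """Transformer computing a :class:`DissimilarityMatrix`.

    Parameters
    ----------
    method : {"mord", "gower", "hamming"}, default="mord"
        Dissimilarity index; MORD is the usual choice for cladistic
        matrices with substantial missing data.
    polymorphism_rule : {"min", "mean"}, default="min"
        How polymorphic state sets enter per-character differences.

    Attributes
    ----------
    dissimilarity_ : DissimilarityMatrix
        Result of the last :meth:`fit`.
    """

    def __init__(self, method: str = "mord", polymorphism_rule: str = "min"):
        self.method = method
        self.polymorphism_rule = polymorphism_rule

    def fit(self, X: CharacterMatrix, y=None) -> "CategoricalDissimilarity":
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if self.polymorphism_rule not in _POLY_RULES:
            raise ValueError(f"polymorphism_rule must be one of {_POLY_RULES}")
        if X.n_taxa < 2:
            raise ValueError("need at least 2 taxa for pairwise dissimilarity")
        self.dissimilarity_ = _compute(X, self.method, self.polymorphism_rule)
        return self

    def transform(self, X: CharacterMatrix) -> DissimilarityMatrix:
        self.fit(X)
        return self.dissimilarity_

    def fit_transform(self, X: CharacterMatrix, y=None) -> DissimilarityMatrix:
        return self.fit(X).dissimilarity_


def pairwise_dissimilarity(
    matrix: CharacterMatrix,
    method: str = "mord",
    polymorphism_rule: str = "min",
) -> DissimilarityMatrix:
    """Functional wrapper around :class:`CategoricalDissimilarity`."""
    return CategoricalDissimilarity(method, polymorphism_rule).fit_transform(matrix)


# ----------------------------------------------------------------------
def _compute(
    matrix: CharacterMatrix, method: str, poly_rule: str
) -> DissimilarityMatrix:
    codes = matrix.codes
    scored = matrix.scored_mask()
    n = matrix.n_taxa
    has_poly = bool((codes == -3).any())
    all_unordered = not matrix.ordering.any()

    if not has_poly and all_unordered:
        # vectorised path: 0/1 mismatches, identical for all three indices
        comp = scored[:, None, :] & scored[None, :, :]
        neq = (codes[:, None, :] != codes[None, :, :]) & comp
        counts = comp.sum(axis=2)
        mism = neq.sum(axis=2)
        with np.errstate(invalid="ignore"):
            values = np.where(counts > 0, mism / np.maximum(counts, 1), np.nan)
        np.fill_diagonal(values, 0.0)
    else:
        values, counts = _compute_general(matrix, method, poly_rule)

    return DissimilarityMatrix(
        tuple(matrix.taxon_labels), values, counts, method, poly_rule
    )


def _compute_general(matrix, method, poly_rule):
    n, m = matrix.shape
    sets = matrix.state_sets()
    ordered = matrix.ordering
    ranges = matrix.character_ranges()
    values = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)

    for i in range(n):
        for k in range(i + 1, n):
            num = 0.0  # Gower: sum of rescaled diffs; MORD: sum of raw diffs
            den = 0.0  # MORD denominator
            mism = 0.0
            n_comp = 0
            for j in range(m):
                a, b = sets[i][j], sets[k][j]
                if not a or not b:
                    continue
                n_comp += 1
                d = _pair_diff(a, b, poly_rule, ordered[j])
                if ordered[j]:
                    rng = ranges[j]
                    if method == "gower":
                        num += d / rng if rng > 0 else 0.0
                    else:
                        num += d
                        den += rng
                else:
                    num += d
                    den += 1.0
                if d > 0:
                    mism += 1.0
            counts[i, k] = counts[k, i] = n_comp
            if n_comp == 0:
                values[i, k] = values[k, i] = np.nan
            elif method == "hamming":
                values[i, k] = values[k, i] = mism / n_comp
            elif method == "gower":
                values[i, k] = values[k, i] = num / n_comp
            else:  # mord
                values[i, k] = values[k, i] = num / den if den > 0 else 0.0
    return values, counts


def _pair_diff(a: frozenset, b: frozenset, rule: str, is_ordered: bool) -> float:
    if rule == "min":
        if a & b:
            return 0.0
        if is_ordered:
            return float(min(abs(x - y) for x in a for y in b))
        return 1.0
    # mean rule
    if is_ordered:
        diffs = [abs(x - y) for x in a for y in b]
    else:
        diffs = [0.0 if x == y else 1.0 for x in a for y in b]
    return float(np.mean(diffs))


# ----------------------------------------------------------------------
def distance_completeness_report(
    D: DissimilarityMatrix, min_comparable: int = 1
) -> dict:
    """Summarise per-pair and per-taxon character comparability.

    Returns a dict with ``per_taxon`` (DataFrame of mean/min comparable
    counts per taxon) and ``sparse_pairs`` (pairs whose comparable-character
    count falls below ``min_comparable``). Never mutates ``D``.
    """
    if D.n_taxa < 2:
        raise ValueError("completeness report needs at least 2 taxa")
    counts = D.comparable_counts.astype(float).copy()
    np.fill_diagonal(counts, np.nan)
    per_taxon = pd.DataFrame(
        {
            "mean_comparable": np.nanmean(counts, axis=1),
            "min_comparable": np.nanmin(counts, axis=1),
        },
        index=list(D.taxon_labels),
    )
    sparse = [
        (D.taxon_labels[i], D.taxon_labels[j], int(D.comparable_counts[i, j]))
        for i in range(D.n_taxa)
        for j in range(i + 1, D.n_taxa)
        if D.comparable_counts[i, j] < min_comparable
    ]
    return {"per_taxon": per_taxon, "sparse_pairs": sparse}
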