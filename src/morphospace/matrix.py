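"""Discrete morphological character matrices and taxon groupings.

A :class:`CharacterMatrix` holds taxa scored for discrete characters whose
states are small non-negative integers. Three kinds of special cell are
supported: missing (``?``), inapplicable (``-``) and polymorphic (a set of
two or more observed states). Missing and inapplicable cells are kept as
distinct tokens even though downstream dissimilarity treats both as
unscored, so alternative treatments of inapplicability remain testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "INAPPLICABLE",
    "CharacterMatrix",
    "TaxonGrouping",
    "MatrixValidationError",
    "filter_outliers",
]


class _Token:
    """Singleton sentinel for a special cell value."""

    __slots__ = ("_name",)

    def __init__(self, name: str):
        self._name = name

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return self._name

    def __deepcopy__(self, memo):
        return self

    def __copy__(self):
        return self


#: Cell scored as unknown ("?").
MISSING = _Token("MISSING")
#: Cell that cannot logically be scored for the taxon ("-").
INAPPLICABLE = _Token("INAPPLICABLE")

# integer codes used in the packed representation
_MISSING_CODE = -1
_INAPPL_CODE = -2
_POLY_CODE = -3


class MatrixValidationError(ValueError):
    """Raised when a character matrix violates its invariants."""


CellValue = object  # int | frozenset[int] | _Token


class CharacterMatrix:
    """Taxa x discrete-characters matrix with special cells.

    Parameters
    ----------
    taxon_labels:
        Ordered, unique, non-empty taxon names.
    cells:
        One row per taxon; each cell is an ``int`` state, ``MISSING``,
        ``INAPPLICABLE``, or a set of >= 2 ``int`` states (polymorphism).
        String shorthand is accepted: ``"?"``, ``"-"``, ``"3"``.
    ordering:
        Per-character flag; ``True`` marks an ordered (additive) character.
        Defaults to all unordered.
    alphabet:
        Declared state symbols. Defaults to the states observed in
        ``cells``; ``{0, 1}`` for an all-special matrix.
    character_labels:
        Optional character names (defaults to ``c1..cN``).
    """

    def __init__(
        self,
        taxon_labels: Sequence[str],
        cells: Sequence[Sequence[CellValue]],
        ordering: Sequence[bool] | None = None,
        alphabet: Iterable[int] | None = None,
        character_labels: Sequence[str] | None = None,
    ):
        taxon_labels = [str(t) for t in taxon_labels]
        if len(taxon_labels) == 0:
            raise MatrixValidationError("matrix must contain at least one taxon")
        if any(not t for t in taxon_labels):
            raise MatrixValidationError("taxon labels must be non-empty")
        if len(set(taxon_labels)) != len(taxon_labels):
            dup = sorted({t for t in taxon_labels if taxon_labels.count(t) > 1})
            raise MatrixValidationError(f"duplicate taxon labels: {dup}")
        if len(cells) != len(taxon_labels):
            raise MatrixValidationError(
                f"{len(taxon_labels)} taxon labels but {len(cells)} rows"
            )

        n_char = len(cells[0]) if cells else 0
        if n_char == 0:
            raise MatrixValidationError("matrix must contain at least one character")

        codes = np.empty((len(taxon_labels), n_char), dtype=np.int16)
        poly: dict[tuple[int, int], frozenset[int]] = {}
        observed: set[int] = set()
        for i, row in enumerate(cells):
            if len(row) != n_char:
                raise MatrixValidationError(
                    f"ragged row for taxon {taxon_labels[i]!r}: "
                    f"{len(row)} cells, expected {n_char}"
                )
            for j, value in enumerate(row):
                code, states = _encode_cell(value, taxon_labels[i], j)
                codes[i, j] = code
                if code == _POLY_CODE:
                    poly[(i, j)] = states
                observed.update(states)

        if alphabet is None:
            alpha = frozenset(observed) if observed else frozenset({0, 1})
        else:
            alpha = frozenset(int(s) for s in alphabet)
            bad = observed - alpha
            if bad:
                offender = _locate_symbol(codes, poly, bad)
                raise MatrixValidationError(
                    f"state(s) {sorted(bad)} not in declared alphabet "
                    f"{sorted(alpha)}; first offending cell at taxon "
                    f"{taxon_labels[offender[0]]!r}, character {offender[1] + 1}"
                )
        if any(s < 0 for s in alpha):
            raise MatrixValidationError("state symbols must be non-negative")

        if ordering is None:
            order_arr = np.zeros(n_char, dtype=bool)
        else:
            order_arr = np.asarray(list(ordering), dtype=bool)
            if order_arr.shape != (n_char,):
                raise MatrixValidationError(
                    f"ordering has length {order_arr.size}, expected {n_char}"
                )

        if character_labels is None:
            char_labels = [f"c{j + 1}" for j in range(n_char)]
        else:
            char_labels = [str(c) for c in character_labels]
            if len(char_labels) != n_char:
                raise MatrixValidationError("character_labels length mismatch")

        self._taxa = taxon_labels
        self._codes = codes
        self._poly = poly
        self._ordering = order_arr
        self._alphabet = alpha
        self._char_labels = char_labels

    # ------------------------------------------------------------------
    @property
    def taxon_labels(self) -> list[str]:
        return list(self._taxa)

    @property
    def character_labels(self) -> list[str]:
        return list(self._char_labels)

    @property
    def n_taxa(self) -> int:
        return len(self._taxa)

    @property
    def n_characters(self) -> int:
        return self._codes.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self._codes.shape

    @property
    def ordering(self) -> np.ndarray:
        """Boolean array; ``True`` marks ordered characters."""
        return self._ordering.copy()

    @property
    def alphabet(self) -> frozenset:
        return self._alphabet

    @property
    def codes(self) -> np.ndarray:
        """Packed integer view: states >= 0, -1 missing, -2 inapplicable,
        -3 polymorphic (sets available via :meth:`cell`)."""
        return self._codes.copy()

    # ------------------------------------------------------------------
    def cell(self, i: int, j: int) -> CellValue:
        """Cell value for taxon ``i``, character ``j``."""
        code = self._codes[i, j]
        if code == _MISSING_CODE:
            return MISSING
        if code == _INAPPL_CODE:
            return INAPPLICABLE
        if code == _POLY_CODE:
            return self._poly[(i, j)]
        return int(code)

    def row(self, taxon: str | int) -> list[CellValue]:
        i = taxon if isinstance(taxon, int) else self._taxa.index(taxon)
        return [self.cell(i, j) for j in range(self.n_characters)]

    def scored_mask(self) -> np.ndarray:
        """Boolean (taxa x characters) mask of scored (non-special or
        polymorphic) cells. Polymorphic cells count as scored."""
        return (self._codes >= 0) | (self._codes == _POLY_CODE)

    def unscored_fraction(self) -> np.ndarray:
        """Per-taxon fraction of MISSING + INAPPLICABLE cells."""
        unscored = (self._codes == _MISSING_CODE) | (self._codes == _INAPPL_CODE)
        return unscored.mean(axis=1)

    def state_sets(self) -> list[list[frozenset]]:
        """Per-cell candidate state sets; empty set for unscored cells."""
        out = []
        for i in range(self.n_taxa):
            row = []
            for j in range(self.n_characters):
                c = self._codes[i, j]
                if c >= 0:
                    row.append(frozenset((int(c),)))
                elif c == _POLY_CODE:
                    row.append(self._poly[(i, j)])
                else:
                    row.append(frozenset())
            out.append(row)
        return out

    def character_ranges(self) -> np.ndarray:
        """Observed state range (max - min) per character, for ordered
        normalisation. Characters with < 2 observed states get range 1."""
        ranges = np.ones(self.n_characters)
        for j in range(self.n_characters):
            states: set[int] = set(self._codes[self._codes[:, j] >= 0, j].tolist())
            for (i, jj), ss in self._poly.items():
                if jj == j:
                    states.update(ss)
            if len(states) >= 2:
                ranges[j] = max(states) - min(states)
        return ranges

    def subset_taxa(self, keep: Sequence[str]) -> "CharacterMatrix":
        """New matrix restricted to ``keep`` (in the given order)."""
        idx = [self._taxa.index(t) for t in keep]
        cells = [[self.cell(i, j) for j in range(self.n_characters)] for i in idx]
        return CharacterMatrix(
            [self._taxa[i] for i in idx],
            cells,
            ordering=self._ordering,
            alphabet=self._alphabet,
            character_labels=self._char_labels,
        )

    # ------------------------------------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self._taxa == other._taxa
            and np.array_equal(self._codes, other._codes)
            and self._poly == other._poly
            and np.array_equal(self._ordering, other._ordering)
        )

    def __repr__(self) -> str:
        return (
            f"<CharacterMatrix {self.n_taxa} taxa x {self.n_characters} "
            f"characters, alphabet {sorted(self._alphabet)}>"
        )


def _encode_cell(value, taxon: str, j: int) -> tuple[int, frozenset]:
    if value is MISSING or (isinstance(value, str) and value == "?"):
        return _MISSING_CODE, frozenset()
    if value is INAPPLICABLE or (isinstance(value, str) and value == "-"):
        return _INAPPL_CODE, frozenset()
    if isinstance(value, (set, frozenset, tuple, list)):
        states = frozenset(int(s) for s in value)
        if len(states) < 2:
            raise MatrixValidationError(
                f"polymorphic cell at taxon {taxon!r}, character {j + 1} "
                f"must contain >= 2 distinct states, got {sorted(states)}"
            )
        if any(s < 0 for s in states):
            raise MatrixValidationError(
                f"negative state in polymorphism at taxon {taxon!r}, "
                f"character {j + 1}"
            )
        return _POLY_CODE, states
    try:
        state = int(value)
    except (TypeError, ValueError):
        raise MatrixValidationError(
            f"unrecognised cell value {value!r} at taxon {taxon!r}, "
            f"character {j + 1}"
        ) from None
    if state < 0:
        raise MatrixValidationError(
            f"negative state {state} at taxon {taxon!r}, character {j + 1}"
        )
    return state, frozenset((state,))


def _locate_symbol(codes, poly, bad: set[int]) -> tuple[int, int]:
    for (i, j), ss in sorted(poly.items()):
        if ss & bad:
            return i, j
    hits = np.argwhere(np.isin(codes, sorted(bad)))
    return tuple(hits[0]) if len(hits) else (0, 0)


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class TaxonGrouping:
    """Map from taxon label to group label, with groups of interest.

    ``groups_of_interest`` defaults to every group present; disparity and
    hypervolume statistics are computed for those groups only, while other
    taxa still contribute to the ordination.
    """

    assignment: Mapping[str, str]
    groups_of_interest: tuple[str, ...] = field(default=())

    def __post_init__(self):
        object.__setattr__(self, "assignment", dict(self.assignment))
        goi = tuple(self.groups_of_interest) or tuple(
            dict.fromkeys(self.assignment.values())
        )
        missing = [g for g in goi if g not in set(self.assignment.values())]
        if missing:
            raise MatrixValidationError(
                f"groups of interest without members: {missing}"
            )
        object.__setattr__(self, "groups_of_interest", goi)

    def members(self, group: str) -> list[str]:
        return [t for t, g in self.assignment.items() if g == group]

    def group_of(self, taxon: str) -> str | None:
        return self.assignment.get(taxon)

    def validate_against(self, matrix: CharacterMatrix) -> None:
        known = set(matrix.taxon_labels)
        unknown = sorted(set(self.assignment) - known)
        if unknown:
            raise MatrixValidationError(
                f"grouped taxa absent from the matrix: {unknown}"
            )

    def restrict_to(self, taxa: Sequence[str]) -> "TaxonGrouping":
        keep = {t: g for t, g in self.assignment.items() if t in set(taxa)}
        goi = tuple(g for g in self.groups_of_interest if g in set(keep.values()))
        return TaxonGrouping(keep, goi)


# ----------------------------------------------------------------------
def filter_outliers(
    matrix: CharacterMatrix, max_missing_fraction: float
) -> tuple[CharacterMatrix, list[tuple[str, float]]]:
    """Remove missing-data-rich taxa.

    A taxon is removed when its fraction of unscored cells (missing plus
    inapplicable) exceeds ``max_missing_fraction``. Returns the filtered
    matrix and a report listing each removed taxon with its fraction.
    Idempotent at a fixed threshold.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must lie in [0, 1]")
    fractions = matrix.unscored_fraction()
    removed = [
        (t, float(f))
        for t, f in zip(matrix.taxon_labels, fractions)
        if f > max_missing_fraction
    ]
    if len(removed) == matrix.n_taxa:
        raise MatrixValidationError(
            f"outlier filter at threshold {max_missing_fraction} would "
            "remove every taxon"
        )
    if not removed:
        return matrix, []
    gone = {t for t, _ in removed}
    keep = [t for t in matrix.taxon_labels if t not in gone]
    return matrix.subset_taxa(keep), removed
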