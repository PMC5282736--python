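"""Reading and writing character matrices and group assignments.

NEXUS parsing is delegated to :mod:`dendropy` (interleaved and
non-interleaved CHARACTERS/DATA blocks; assumptions and trees blocks are
ignored). Writing produces a plain non-interleaved block that round-trips
through the reader. CSV matrices use a simple dialect: first column is the
taxon label, the header row carries character ids, and cells are state
symbols, ``?`` (missing), ``-`` (inapplicable) or ``{01}``-style
polymorphism sets.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import dendropy
import pandas as pd

from .matrix import (
    INAPPLICABLE,
    MISSING,
    CharacterMatrix,
    MatrixValidationError,
    TaxonGrouping,
)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_groups",
    "write_groups",
    "MatrixParseError",
]


class MatrixParseError(ValueError):
    """Raised when a matrix file cannot be parsed."""


def read_matrix(path: str | Path, format: str | None = None) -> CharacterMatrix:
    """Read a character matrix from NEXUS or CSV.

    ``format`` is ``"nexus"`` or ``"csv"``; if omitted it is inferred from
    the file suffix (``.nex``/``.nexus`` vs ``.csv``).
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "nexus":
        return _read_nexus(path)
    if fmt == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown matrix format {fmt!r}")


def write_matrix(
    matrix: CharacterMatrix, path: str | Path, format: str | None = None
) -> None:
    """Write a matrix so that :func:`read_matrix` recovers it cell-for-cell."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "nexus":
        path.write_text(_format_nexus(matrix))
    elif fmt == "csv":
        _write_csv(matrix, path)
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".nex", ".nexus", ".nxs"}:
        return "nexus"
    if suffix in {".csv", ".tsv"}:
        return "csv"
    raise ValueError(
        f"cannot infer matrix format from suffix {suffix!r}; pass format="
    )


# ----------------------------------------------------------------------
# NEXUS
# ----------------------------------------------------------------------
def _read_nexus(path: Path) -> CharacterMatrix:
    try:
        data = dendropy.StandardCharacterMatrix.get(
            path=str(path), schema="nexus"
        )
    except Exception as exc:  # dendropy raises assorted error classes
        raise MatrixParseError(f"failed to parse NEXUS file {path}: {exc}") from exc

    alphabet = {
        int(s.symbol)
        for s in data.default_state_alphabet.fundamental_state_iter()
        if s.symbol not in ("-", "?") and s.symbol.isdigit()
    }

    taxa: list[str] = []
    cells: list[list] = []
    for taxon in data.taxon_namespace:
        seq = data[taxon]
        row = []
        for j, st in enumerate(seq):
            row.append(_decode_state(st, taxon.label, j, alphabet))
        taxa.append(taxon.label)
        cells.append(row)

    lengths = {len(r) for r in cells}
    if len(lengths) > 1:
        ragged = [t for t, r in zip(taxa, cells) if len(r) != max(lengths)]
        raise MatrixParseError(
            f"ragged NEXUS matrix in {path}: taxa {ragged} differ in length"
        )
    try:
        return CharacterMatrix(taxa, cells, alphabet=alphabet or None)
    except MatrixValidationError as exc:
        raise MatrixParseError(f"invalid matrix in {path}: {exc}") from exc


def _decode_state(st, taxon: str, j: int, alphabet: set):
    symbol = st.symbol
    if symbol == "?":
        return MISSING
    if symbol == "-":
        return INAPPLICABLE
    if symbol is not None and st.state_denomination == 0:
        if not symbol.isdigit():
            raise MatrixParseError(
                f"non-numeric state symbol {symbol!r} at taxon {taxon!r}, "
                f"character {j + 1}"
            )
        return int(symbol)
    members = {m.symbol for m in (st.member_states or [])}
    members.discard("-")
    if not members or members == {str(s) for s in alphabet}:
        # full-alphabet ambiguity is equivalent to missing
        return MISSING
    if any(not m.isdigit() for m in members):
        raise MatrixParseError(
            f"non-numeric state in set {sorted(members)} at taxon "
            f"{taxon!r}, character {j + 1}"
        )
    states = frozenset(int(m) for m in members)
    if len(states) == 1:
        return next(iter(states))
    return states


def _format_cell(value) -> str:
    if value is MISSING:
        return "?"
    if value is INAPPLICABLE:
        return "-"
    if isinstance(value, frozenset):
        return "{" + "".join(str(s) for s in sorted(value)) + "}"
    return str(value)


def _format_nexus(matrix: CharacterMatrix) -> str:
    states = sorted(matrix.alphabet)
    if any(s > 9 for s in states):
        raise ValueError("NEXUS output supports single-digit states (0-9) only")
    symbols = "".join(str(s) for s in states)
    width = max(len(t) for t in matrix.taxon_labels) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};",
        f'    FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;',
        "    MATRIX",
    ]
    for i, taxon in enumerate(matrix.taxon_labels):
        label = _nexus_label(taxon)
        row = "".join(_format_cell(matrix.cell(i, j)) for j in range(matrix.n_characters))
        lines.append(f"    {label:<{width}}{row}")
    lines += ["    ;", "END;", ""]
    return "\n".join(lines)


def _nexus_label(label: str) -> str:
    # underscores must be quoted: unquoted they denote spaces in NEXUS
    if re.search(r"[\s_(){}\[\];,'\"]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


# ----------------------------------------------------------------------
# CSV
# ----------------------------------------------------------------------
_POLY_RE = re.compile(r"^[{(]([0-9]{2,})[)}]$")


def _read_csv(path: Path) -> CharacterMatrix:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, index_col=0)
    if df.shape[1] == 0:
        raise MatrixParseError(f"no character columns in {path}")
    taxa = [str(t) for t in df.index]
    cells = []
    for i, taxon in enumerate(taxa):
        row = []
        for j, raw in enumerate(df.iloc[i]):
            raw = str(raw).strip()
            if raw == "?":
                row.append(MISSING)
            elif raw == "-":
                row.append(INAPPLICABLE)
            elif (m := _POLY_RE.match(raw)) is not None:
                row.append(frozenset(int(c) for c in m.group(1)))
            elif raw.isdigit():
                row.append(int(raw))
            else:
                raise MatrixParseError(
                    f"unrecognised cell {raw!r} at taxon {taxon!r}, "
                    f"character {df.columns[j]!r} in {path}"
                )
        cells.append(row)
    try:
        return CharacterMatrix(
            taxa, cells, character_labels=[str(c) for c in df.columns]
        )
    except MatrixValidationError as exc:
        raise MatrixParseError(f"invalid matrix in {path}: {exc}") from exc


def _write_csv(matrix: CharacterMatrix, path: Path) -> None:
    rows = {
        taxon: [
            _format_cell(matrix.cell(i, j)) for j in range(matrix.n_characters)
        ]
        for i, taxon in enumerate(matrix.taxon_labels)
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=matrix.character_labels)
    df.index.name = "taxon"
    df.to_csv(path)


# ----------------------------------------------------------------------
# group assignments
# ----------------------------------------------------------------------
def read_groups(
    path: str | Path, groups_of_interest: Sequence[str] = ()
) -> TaxonGrouping:
    """Read a two-column (taxon, group) CSV into a :class:`TaxonGrouping`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise MatrixParseError(f"group file {path} needs (taxon, group) columns")
    assignment = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    return TaxonGrouping(assignment, tuple(groups_of_interest))


def write_groups(grouping: TaxonGrouping, path: str | Path) -> None:
    df = pd.DataFrame(
        sorted(grouping.assignment.items()), columns=["taxon", "group"]
    )
    df.to_csv(path, index=False)
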