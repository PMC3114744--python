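"""Core sequence and alignment containers.

All coordinates are 0-based; intervals are half-open ``[start, end)``.
Alignment rows are gapped strings over ``{A, C, G, T, N, -}``; the
*projection* of a row (the row with gaps removed) must always equal the
unaligned input sequence — this conservation invariant is enforced
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import InvalidInputError

GAP = "-"
DNA_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """A named, unaligned DNA sequence."""

    name: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise InvalidInputError(
                f"sequence {self.name!r} contains non-DNA characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


class MultipleAlignment:
    """Rows (named sequences) by columns of residues and gaps.

    Invariants: all rows have equal length; no column is all-gap; row
    names are unique.
    """

    __slots__ = ("_names", "_rows", "_index")

    def __init__(
        self,
        names: Sequence[str],
        rows: Sequence[str],
        *,
        validate: bool = True,
    ) -> None:
        if len(names) != len(rows):
            raise InvalidInputError("names and rows differ in length")
        self._names = list(names)
        self._rows = list(rows)
        self._index = {n: i for i, n in enumerate(self._names)}
        if validate:
            self._validate()

    def _validate(self) -> None:
        if len(self._index) != len(self._names):
            raise InvalidInputError("duplicate row names in alignment")
        if self._rows:
            ncol = len(self._rows[0])
            for name, row in zip(self._names, self._rows):
                if len(row) != ncol:
                    raise InvalidInputError(
                        f"ragged alignment: row {name!r} has length "
                        f"{len(row)} != {ncol}"
                    )
                bad = set(row) - DNA_ALPHABET - {GAP}
                if bad:
                    raise InvalidInputError(
                        f"row {name!r} contains invalid characters: {sorted(bad)}"
                    )

    # -- construction -------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[SequenceRecord]) -> "MultipleAlignment":
        """Single-row-per-record alignment; all records must share one length."""
        records = list(records)
        return cls([r.name for r in records], [r.residues for r in records])

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "MultipleAlignment":
        pairs = list(pairs)
        return cls([p[0] for p in pairs], [p[1] for p in pairs])

    # -- basic accessors ----------------------------------------------

    @property
    def names(self) -> list[str]:
        return list(self._names)

    @property
    def n_rows(self) -> int:
        return len(self._names)

    @property
    def n_cols(self) -> int:
        return len(self._rows[0]) if self._rows else 0

    def row(self, name: str) -> str:
        try:
            return self._rows[self._index[name]]
        except KeyError:
            raise InvalidInputError(f"no row named {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self._names, self._rows))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultipleAlignment):
            return NotImplemented
        return self._names == other._names and self._rows == other._rows

    def __repr__(self) -> str:
        return f"<MultipleAlignment {self.n_rows} rows x {self.n_cols} cols>"

    # -- derived views ------------------------------------------------

    def projection(self, name: str) -> str:
        """The row with gaps removed (must equal the input sequence)."""
        return self.row(name).replace(GAP, "")

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self._rows)

    def reorder(self, names: Sequence[str]) -> "MultipleAlignment":
        return MultipleAlignment(
            list(names), [self.row(n) for n in names], validate=False
        )

    def subset(self, names: Sequence[str], *, drop_gap_columns: bool = True):
        """Alignment restricted to ``names``; all-gap columns optionally dropped."""
        rows = [self.row(n) for n in names]
        aln = MultipleAlignment(list(names), rows, validate=False)
        return aln.drop_all_gap_columns() if drop_gap_columns else aln

    def drop_all_gap_columns(self) -> "MultipleAlignment":
        if not self._rows:
            return self
        keep = [
            j
            for j in range(self.n_cols)
            if any(row[j] != GAP for row in self._rows)
        ]
        if len(keep) == self.n_cols:
            return self
        rows = ["".join(row[j] for j in keep) for row in self._rows]
        return MultipleAlignment(self._names, rows, validate=False)

    # -- invariant checks ---------------------------------------------

    def check_projection(self, records: Mapping[str, str]) -> None:
        """Raise unless every row projects to its source sequence."""
        for name in self._names:
            expected = records.get(name)
            if expected is None:
                raise InvalidInputError(f"no source sequence for row {name!r}")
            if self.projection(name) != expected:
                raise InvalidInputError(
                    f"row {name!r} does not project to its input sequence"
                )


def concatenate(pieces: Sequence[MultipleAlignment], names: Sequence[str]) -> MultipleAlignment:
    """Concatenate alignment pieces column-wise over a fixed row universe.

    Rows absent from a piece are padded with gaps for that piece's columns.
    """
    parts: dict[str, list[str]] = {n: [] for n in names}
    for piece in pieces:
        ncol = piece.n_cols
        for n in names:
            parts[n].append(piece.row(n) if n in piece else GAP * ncol)
    rows = ["".join(parts[n]) for n in names]
    aln = MultipleAlignment(list(names), rows, validate=False)
    return aln.drop_all_gap_columns()
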