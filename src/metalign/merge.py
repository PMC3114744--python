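"""Merging sub-alignments through guide rows.

A *guide row* is a row of a parent alignment whose residues map, one for
one, onto columns of a child alignment (the child's inferred root
sequence). Merging splices each child column into the parent column that
carries the corresponding guide residue. Child columns never reached by
the guide map (possible when the guide is a leaf sequence rather than a
column consensus) are inserted as new columns, gapped everywhere else,
immediately before the next mapped column.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .errors import InternalConsistencyError, InvalidInputError
from .msa import GAP, MultipleAlignment


def merge_alignments(
    parent: MultipleAlignment,
    guides: Mapping[str, tuple[MultipleAlignment, Sequence[int]]],
    *,
    keep_internal: bool = False,
) -> tuple[MultipleAlignment, list[int]]:
    """Splice child alignments into a parent through guide rows.

    Parameters
    ----------
    parent
        The alignment whose columns set the global frame.
    guides
        Maps a guide row name of ``parent`` to ``(child, col_map)`` where
        ``col_map[r]`` is the child column holding residue ``r`` of the
        guide sequence. ``col_map`` must be strictly increasing.
    keep_internal
        Keep the guide rows in the output (default: remove them).

    Returns
    -------
    (merged, parent_col_map)
        ``parent_col_map[c]`` is the output column index that parent
        column ``c`` landed on, or -1 if it was dropped as all-gap.
    """
    guide_names = list(guides)
    for g in guide_names:
        if g not in parent:
            raise InvalidInputError(f"guide row {g!r} not in parent alignment")
        child, cmap = guides[g]
        n_res = len(parent.projection(g))
        if len(cmap) != n_res:
            raise InternalConsistencyError(
                f"guide {g!r}: {n_res} residues but {len(cmap)} mapped columns"
            )
        for a, b in zip(cmap, list(cmap)[1:]):
            if b <= a:
                raise InternalConsistencyError(f"guide {g!r}: non-monotone column map")
        if cmap and not (0 <= cmap[0] and cmap[-1] < child.n_cols):
            raise InternalConsistencyError(f"guide {g!r}: column map out of range")

    # output row universe, preserving parent row order; each guide row is
    # replaced in place by its child's rows
    out_names: list[str] = []
    for name in parent.names:
        if name in guides:
            if keep_internal:
                out_names.append(name)
            out_names.extend(guides[name][0].names)
        else:
            out_names.append(name)
    if len(set(out_names)) != len(out_names):
        raise InvalidInputError("row name collision while merging")

    cells: dict[str, list[str]] = {n: [] for n in out_names}
    n_out = 0

    def emit(column: Mapping[str, str]) -> None:
        nonlocal n_out
        for name in out_names:
            cells[name].append(column.get(name, GAP))
        n_out += 1

    res_count = {g: 0 for g in guide_names}
    last_col = {g: -1 for g in guide_names}

    def emit_child_cols(g: str, upto: int) -> None:
        """Emit unmapped child columns (last_col, upto) as standalone columns."""
        child, _ = guides[g]
        for j in range(last_col[g] + 1, upto):
            emit({name: child.row(name)[j] for name in child.names})
        last_col[g] = max(last_col[g], upto - 1)

    parent_col_map: list[int] = []
    guide_rows = {g: parent.row(g) for g in guide_names}
    for c in range(parent.n_cols):
        mapped: dict[str, int] = {}
        for g in guide_names:
            if guide_rows[g][c] != GAP:
                j = guides[g][1][res_count[g]]
                emit_child_cols(g, j)
                mapped[g] = j
                res_count[g] += 1
        column: dict[str, str] = {}
        for name in parent.names:
            if name in guides:
                if keep_internal:
                    column[name] = parent.row(name)[c]
                child, _ = guides[name]
                if name in mapped:
                    j = mapped[name]
                    for rn in child.names:
                        column[rn] = child.row(rn)[j]
                    last_col[name] = j
            else:
                column[name] = parent.row(name)[c]
        parent_col_map.append(n_out)
        emit(column)
    for g in guide_names:
        emit_child_cols(g, guides[g][0].n_cols)

    rows = ["".join(cells[n]) for n in out_names]
    merged = MultipleAlignment(out_names, rows, validate=False)
    keep = [j for j in range(n_out) if any(r[j] != GAP for r in rows)]
    if len(keep) != n_out:
        remap = {old: new for new, old in enumerate(keep)}
        merged = merged.drop_all_gap_columns()
        parent_col_map = [remap.get(c, -1) for c in parent_col_map]
    return merged, parent_col_map
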