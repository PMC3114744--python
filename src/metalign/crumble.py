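"""Length-wise partitioning of an alignment problem via constraint-induced
separations.

Given a consistent set of sparse alignment constraints, a *separation*
anchored at a base position ``x`` is, per species, the interval from the
greatest position comparable-below ``x`` to the least position
comparable-above ``x``. Nothing strictly before a separation can be
aligned with anything strictly after it without contradicting the
constraint partial order, so the regions between consecutive separations
(*cores*) are mutually unalignable and can be aligned independently. A
*block* is a core plus its two flanking separations — the unit handed to
the aligner. After block alignment, the shared separations are trimmed
off both neighbours, realigned on their own, and everything is
concatenated in order.

Species with no constraint bounding a region get separations that extend
to their sequence ends; a user-set maximum block size then truncates
oversized blocks (the truncated sequence becomes part of the next block,
and the independence guarantee is void across truncated boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

from .aligners import AlignerBackend
from .constraints import ConstraintSet, Position, check_consistency
from .errors import InternalConsistencyError, InvalidInputError
from .executor import ExecutorConfig, Job
from .msa import GAP, MultipleAlignment, SequenceRecord, concatenate


@dataclass
class Separation:
    """Per-species half-open residue interval ``[start, end)``.

    May be empty for a species. The invariant: no residue strictly before
    a start is comparable-after any residue at-or-after the corresponding
    end under the constraint partial order.
    """

    intervals: dict[str, tuple[int, int]]

    def start(self, name: str) -> int:
        return self.intervals[name][0]

    def end(self, name: str) -> int:
        return self.intervals[name][1]

    def width(self, name: str) -> int:
        lo, hi = self.intervals[name]
        return hi - lo

    def is_empty(self) -> bool:
        return all(lo >= hi for lo, hi in self.intervals.values())


@dataclass
class Block:
    """A core plus its flanking separations; ``interval`` covers all three."""

    index: int
    interval: dict[str, tuple[int, int]]
    left: Optional[Separation]   # absent at the left problem edge
    right: Optional[Separation]  # absent at the right problem edge

    def core(self, name: str) -> tuple[int, int]:
        lo = self.left.end(name) if self.left is not None else self.interval[name][0]
        hi = self.right.start(name) if self.right is not None else self.interval[name][1]
        return lo, max(lo, hi)


@dataclass
class BlockTiling:
    blocks: list[Block]
    constraints: ConstraintSet

    def __len__(self) -> int:
        return len(self.blocks)


def find_separation(cs: ConstraintSet, anchor: Position) -> Separation:
    """The separation through ``anchor`` under the constraint partial order.

    Per species: the least position at-or-after the anchor (its sequence
    end when none exists) closes the interval; the greatest position
    at-or-before the anchor (its sequence start when none exists) opens
    it. A fully aligned column therefore yields width-1 intervals in
    every species; an empty constraint set yields intervals spanning
    whole sequences except in the anchor's own species.
    """
    ok, _ = check_consistency(cs)
    if not ok:
        raise InvalidInputError("constraint set is inconsistent")
    name, pos = anchor
    if name not in cs.lengths:
        raise InvalidInputError(f"unknown sequence {name!r}")
    if not 0 <= pos < cs.lengths[name]:
        raise InvalidInputError(f"anchor position {pos} out of range")
    upper = cs.poset.upper_bounds(anchor)
    lower = cs.poset.lower_bounds(anchor)
    intervals = {}
    for seq, length in cs.lengths.items():
        hi = upper[seq] + 1 if upper[seq] is not None else length
        lo = lower[seq] if lower[seq] is not None else 0
        intervals[seq] = (min(lo, hi), hi)
    return Separation(intervals)


def tile_blocks(
    cs: ConstraintSet, core_size: int, max_block_size: Optional[int] = None
) -> BlockTiling:
    """Greedy left-to-right tiling of the constraints into blocks.

    The scan is paced by the first sequence in input order (the
    reference): each step advances roughly ``core_size`` residues past the
    previous separation's end there and drops a separation at that
    anchor. Any block exceeding ``max_block_size`` residues in a species
    is cut at the cap in that species; a cut empties the shared boundary
    so the truncated sequence becomes part of the next block. The last
    block absorbs all remainders (chunked at the cap when one is set).
    """
    if core_size <= 0:
        raise InvalidInputError("core_size must be positive")
    if max_block_size is not None and max_block_size < core_size:
        raise InvalidInputError("max_block_size must be >= core_size")
    names = cs.names()
    if not names:
        return BlockTiling([], cs)
    ref = names[0]
    lengths = cs.lengths

    prev = Separation({n: (0, 0) for n in names})  # virtual start boundary
    boundaries: list[Separation] = []
    while True:
        anchor_pos = prev.end(ref) + core_size
        if anchor_pos >= lengths[ref]:
            break
        sep = find_separation(cs, (ref, anchor_pos))
        intervals = {}
        truncated = False
        for n in names:
            lo, hi = sep.intervals[n]
            lo = max(lo, prev.end(n))
            hi = max(hi, lo)
            if max_block_size is not None and hi - prev.start(n) > max_block_size:
                cut = prev.start(n) + max_block_size
                lo = hi = max(cut, prev.end(n))
                truncated = True
            intervals[n] = (lo, hi)
        boundaries.append(Separation(intervals))
        prev = boundaries[-1]
        del truncated

    # final block(s): absorb remainders, still honouring the size cap
    if max_block_size is not None:
        while any(
            lengths[n] - prev.start(n) > max_block_size for n in names
        ):
            intervals = {}
            for n in names:
                cut = min(prev.start(n) + max_block_size, lengths[n])
                cut = max(cut, prev.end(n))
                intervals[n] = (cut, cut)
            boundaries.append(Separation(intervals))
            prev = boundaries[-1]

    blocks: list[Block] = []
    bounds = [Separation({n: (0, 0) for n in names})] + boundaries + [
        Separation({n: (lengths[n], lengths[n]) for n in names})
    ]
    for k in range(len(bounds) - 1):
        left, right = bounds[k], bounds[k + 1]
        interval = {n: (left.start(n), right.end(n)) for n in names}
        blocks.append(
            Block(
                index=k,
                interval=interval,
                left=left if k > 0 else None,
                right=right if k < len(bounds) - 2 else None,
            )
        )
    return BlockTiling(blocks, cs)


def trim_block_alignment(
    aln: MultipleAlignment,
    side: Literal["left", "right"],
    sep: Separation,
    offsets: dict[str, int],
) -> tuple[MultipleAlignment, dict[str, str]]:
    """Remove a separation's residues from one flank of a block alignment.

    ``offsets[name]`` is the residue index (in the full sequence) of the
    first residue of row ``name`` in this block. The separation residues
    must form a contiguous prefix (``side='left'``) or suffix
    (``side='right'``) of each row's residues; they are replaced by gaps,
    all-gap columns are dropped, and the removed residues are returned
    per species in sequence order.
    """
    if side not in ("left", "right"):
        raise InvalidInputError(f"side must be 'left' or 'right', got {side!r}")
    kept_rows: list[str] = []
    removed: dict[str, str] = {}
    for name in aln.names:
        row = aln.row(name)
        n_res = len(row) - row.count(GAP)
        if name in sep.intervals:
            lo, hi = sep.intervals[name]
            lo = max(lo, offsets[name])
            count = max(0, hi - lo)
        else:
            count = 0
        if count > n_res:
            raise InternalConsistencyError(
                f"separation wider than row {name!r} in block"
            )
        if side == "left":
            keep_range = range(count, n_res)
        else:
            keep_range = range(0, n_res - count)
        out = []
        removed_chars = []
        r = 0
        for ch in row:
            if ch == GAP:
                out.append(GAP)
            else:
                if r in keep_range:
                    out.append(ch)
                else:
                    out.append(GAP)
                    removed_chars.append(ch)
                r += 1
        kept_rows.append("".join(out))
        removed[name] = "".join(removed_chars)
    kept = MultipleAlignment(aln.names, kept_rows, validate=False)
    return kept.drop_all_gap_columns(), removed


def crumble_align(
    seqs: Sequence[SequenceRecord],
    cs: ConstraintSet,
    backend: AlignerBackend,
    core_size: int,
    max_block_size: Optional[int] = None,
    executor: Optional[ExecutorConfig] = None,
) -> MultipleAlignment:
    """The full length-wise pipeline: tile, align blocks in parallel, trim
    the shared separations, realign them standalone, and concatenate.

    With a single block the result is exactly the backend's direct
    alignment. Every output row projects to its input sequence.
    """
    if executor is None:
        executor = ExecutorConfig(jobs=1)
    seqs = list(seqs)
    if not seqs:
        return MultipleAlignment([], [])
    names = [s.name for s in seqs]
    by_name = {s.name: s for s in seqs}
    if set(cs.lengths) != set(names):
        raise InvalidInputError("constraint set does not cover the input sequences")
    ok, _ = check_consistency(cs)
    if not ok:
        raise InvalidInputError("constraint set is inconsistent")

    tiling = tile_blocks(cs, core_size, max_block_size)
    blocks = tiling.blocks
    block_alns: dict[int, MultipleAlignment] = {}
    sep_alns: dict[int, MultipleAlignment] = {}

    def align_block(block: Block) -> None:
        records = []
        for n in names:
            lo, hi = block.interval[n]
            if hi > lo:
                records.append(SequenceRecord(n, by_name[n].residues[lo:hi]))
        try:
            block_alns[block.index] = backend.align(records)
        except Exception as exc:
            raise InternalConsistencyError(
                f"backend failed on block {block.index}: {exc}"
            ) from exc

    def realign_separation(k: int, sep: Separation) -> None:
        records = [
            SequenceRecord(n, by_name[n].residues[lo:hi])
            for n, (lo, hi) in sep.intervals.items()
            if hi > lo
        ]
        if len(records) <= 1:
            # nothing to align; emit directly
            sep_alns[k] = MultipleAlignment.from_records(records)
            return
        try:
            sep_alns[k] = backend.align(records)
        except Exception as exc:
            raise InternalConsistencyError(
                f"backend failed on separation {k}: {exc}"
            ) from exc

    def spawn_block_jobs(job: Job) -> None:
        for block in blocks:
            job.add_child(
                Job(f"block-{block.index}", action=lambda _j, b=block: align_block(b))
            )

    def spawn_separation_jobs(job: Job) -> None:
        for k, block in enumerate(blocks[:-1]):
            sep = block.right
            assert sep is not None
            job.add_child(
                Job(
                    f"separation-{k}",
                    action=lambda _j, k=k, s=sep: realign_separation(k, s),
                )
            )

    root = Job("crumble", action=spawn_block_jobs)
    root.set_follow_on(Job("realign-separations", action=spawn_separation_jobs))
    executor.run(root)

    # trim both flanks of every internal boundary
    pieces: list[MultipleAlignment] = []
    for block in blocks:
        aln = block_alns[block.index]
        offsets = {n: block.interval[n][0] for n in names}
        if block.left is not None and not block.left.is_empty():
            aln, _ = trim_block_alignment(aln, "left", block.left, offsets)
        if block.right is not None and not block.right.is_empty():
            aln, _ = trim_block_alignment(aln, "right", block.right, offsets)
        pieces.append(aln)

    interleaved: list[MultipleAlignment] = []
    for k, block in enumerate(blocks):
        interleaved.append(pieces[k])
        if k in sep_alns:
            interleaved.append(sep_alns[k])
    result = concatenate(interleaved, names)
    result.check_projection({s.name: s.residues for s in seqs})
    return result
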