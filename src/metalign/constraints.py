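"""Sparse pairwise alignment constraints and the partial order they induce.

A *constraint* aligns one base position in one sequence with one base
position in another sequence. A set of such constraints is a sparse
alignment: aligned positions are equal under the induced relation, and
positions along one sequence increase. The set is *consistent* when that
relation is a partial order, i.e. when the graph whose nodes are
equivalence classes of aligned positions (with directed edges for
within-sequence order) is acyclic.

Positions are ``(sequence_name, 0-based index)`` pairs throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import networkx as nx

from .errors import InvalidInputError
from .msa import SequenceRecord

Position = tuple[str, int]


@dataclass(frozen=True, order=True)
class Constraint:
    """An unordered aligned pair of base positions in two sequences.

    Stored in canonical orientation: ``(seq_a, pos_a) < (seq_b, pos_b)``
    lexicographically, so symmetric duplicates collapse.
    """

    seq_a: str
    pos_a: int
    seq_b: str
    pos_b: int

    @staticmethod
    def make(seq_a: str, pos_a: int, seq_b: str, pos_b: int) -> "Constraint":
        if seq_a == seq_b:
            raise InvalidInputError(
                f"constraint must join two different sequences, got {seq_a!r} twice"
            )
        if (seq_a, pos_a) > (seq_b, pos_b):
            seq_a, pos_a, seq_b, pos_b = seq_b, pos_b, seq_a, pos_a
        return Constraint(seq_a, pos_a, seq_b, pos_b)

    def positions(self) -> tuple[Position, Position]:
        return (self.seq_a, self.pos_a), (self.seq_b, self.pos_b)


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[Position, Position] = {}

    def find(self, x: Position) -> Position:
        parent = self.parent
        if x not in parent:
            parent[x] = x
            return x
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def union(self, a: Position, b: Position) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller tuple becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


class ConstraintSet:
    """Sequences plus a deduplicated, symmetric set of position constraints."""

    def __init__(
        self,
        sequences: Sequence[SequenceRecord],
        constraints: Iterable[Constraint] = (),
    ) -> None:
        self.sequences = list(sequences)
        names = [s.name for s in self.sequences]
        if len(set(names)) != len(names):
            raise InvalidInputError("duplicate sequence names")
        self.lengths = {s.name: len(s) for s in self.sequences}
        self.constraints: set[Constraint] = set()
        for c in constraints:
            self._check_range(c)
            self.constraints.add(c)
        self._poset: Optional[_PositionPoset] = None

    def _check_range(self, c: Constraint) -> None:
        for name, pos in c.positions():
            if name not in self.lengths:
                raise InvalidInputError(f"unknown sequence {name!r} in constraint")
            if not 0 <= pos < self.lengths[name]:
                raise InvalidInputError(
                    f"position {pos} out of range for sequence {name!r}"
                )

    def names(self) -> list[str]:
        return [s.name for s in self.sequences]

    def replace_constraints(self, constraints: Iterable[Constraint]) -> "ConstraintSet":
        return ConstraintSet(self.sequences, constraints)

    # -- the induced partial order --------------------------------------

    @property
    def poset(self) -> "_PositionPoset":
        if self._poset is None:
            self._poset = _PositionPoset(self)
        return self._poset

    def __len__(self) -> int:
        return len(self.constraints)

    def __repr__(self) -> str:
        return (
            f"<ConstraintSet {len(self.sequences)} sequences, "
            f"{len(self.constraints)} constraints>"
        )


class _PositionPoset:
    """Equivalence classes of aligned positions plus within-sequence order.

    Only positions touched by a constraint get explicit classes; untouched
    positions are ordered through their constrained neighbours along the
    same sequence.
    """

    def __init__(self, cs: ConstraintSet) -> None:
        self.cs = cs
        uf = _UnionFind()
        for c in cs.constraints:
            p, q = c.positions()
            uf.union(p, q)
        self.class_of: dict[Position, Position] = {
            p: uf.find(p) for c in cs.constraints for p in c.positions()
        }
        # constrained positions per sequence, sorted by index
        self.anchored: dict[str, list[int]] = {n: [] for n in cs.lengths}
        seen: dict[str, set[int]] = {n: set() for n in cs.lengths}
        for (name, pos) in self.class_of:
            if pos not in seen[name]:
                seen[name].add(pos)
                self.anchored[name].append(pos)
        for name in self.anchored:
            self.anchored[name].sort()
        # class members grouped by sequence
        self.members: dict[Position, dict[str, list[int]]] = {}
        for (name, pos), cls in self.class_of.items():
            self.members.setdefault(cls, {}).setdefault(name, []).append(pos)
        for by_seq in self.members.values():
            for positions in by_seq.values():
                positions.sort()

    def graph(self) -> nx.DiGraph:
        """Directed graph over classes: equality collapsed, strict order as edges."""
        g = nx.DiGraph()
        g.add_nodes_from(self.members)
        for name, positions in self.anchored.items():
            for lo, hi in zip(positions, positions[1:]):
                a = self.class_of[(name, lo)]
                b = self.class_of[(name, hi)]
                g.add_edge(a, b)
            # same class twice in one sequence == an immediate cycle
        for cls, by_seq in self.members.items():
            for positions in by_seq.values():
                if len(positions) > 1:
                    g.add_edge(cls, cls)
        return g

    # -- reachability frontiers ------------------------------------------

    def _fixpoint(self, start: dict[str, int], *, up: bool) -> dict[str, Optional[int]]:
        """Per sequence, the extreme position comparable with the start set.

        ``up=True``: least position ``a`` per sequence with start ≼ a.
        ``up=False``: greatest position ``b`` per sequence with b ≼ start.
        ``start`` maps sequence name -> known bound in that sequence.
        """
        import bisect

        best: dict[str, Optional[int]] = {n: None for n in self.cs.lengths}

        def better(new: int, old: Optional[int]) -> bool:
            if old is None:
                return True
            return new < old if up else new > old

        # processed window per sequence: anchored positions already expanded
        # (propagation is idempotent, so each expands at most once per query)
        if up:
            ptr = {n: len(a) for n, a in self.anchored.items()}
        else:
            ptr = {n: -1 for n in self.anchored}
        work = []
        for name, pos in start.items():
            best[name] = pos
            work.append(name)
        while work:
            name = work.pop()
            bound = best[name]
            assert bound is not None
            anchored = self.anchored[name]
            if up:
                idx = bisect.bisect_left(anchored, bound)
                lo, hi = idx, ptr[name]
                ptr[name] = min(ptr[name], idx)
            else:
                idx = bisect.bisect_right(anchored, bound)
                lo, hi = ptr[name] + 1, idx
                ptr[name] = max(ptr[name], idx - 1)
            for pos in anchored[lo:hi]:
                cls = self.class_of[(name, pos)]
                for other, positions in self.members[cls].items():
                    cand = positions[0] if up else positions[-1]
                    if better(cand, best[other]):
                        best[other] = cand
                        work.append(other)
        return best

    def upper_bounds(self, p: Position) -> dict[str, Optional[int]]:
        """Least position per sequence at-or-after ``p`` in the partial order."""
        name, pos = p
        cls = self.class_of.get(p)
        if cls is not None:
            start = {n: positions[0] for n, positions in self.members[cls].items()}
        else:
            start = {name: pos}
        return self._fixpoint(start, up=True)

    def lower_bounds(self, p: Position) -> dict[str, Optional[int]]:
        """Greatest position per sequence at-or-before ``p``."""
        name, pos = p
        cls = self.class_of.get(p)
        if cls is not None:
            start = {n: positions[-1] for n, positions in self.members[cls].items()}
        else:
            start = {name: pos}
        return self._fixpoint(start, up=False)


def check_consistency(cs: ConstraintSet) -> tuple[bool, list[Constraint]]:
    """True iff the induced relation is a partial order.

    The second element lists the constraints implicated in cycles (both
    endpoints inside one non-trivial strongly connected component); empty
    when consistent.
    """
    poset = cs.poset
    g = poset.graph()
    bad_nodes: set[Position] = set()
    for comp in nx.strongly_connected_components(g):
        if len(comp) > 1 or any(g.has_edge(n, n) for n in comp):
            bad_nodes.update(comp)
    if not bad_nodes:
        return True, []
    scc_id: dict[Position, int] = {}
    for i, comp in enumerate(nx.strongly_connected_components(g)):
        for n in comp:
            scc_id[n] = i
    violating = []
    for c in sorted(cs.constraints):
        ca = poset.class_of[(c.seq_a, c.pos_a)]
        cb = poset.class_of[(c.seq_b, c.pos_b)]
        if ca in bad_nodes and cb in bad_nodes and scc_id[ca] == scc_id[cb]:
            violating.append(c)
    return False, violating


def precedes(
    cs: ConstraintSet, p: Position, q: Position
) -> Literal["before", "after", "equal", "incomparable"]:
    """Order of two positions under the constraint partial order.

    Requires a consistent constraint set. Same-sequence positions compare
    by index; cross-sequence positions compare by reachability through
    the aligned-position classes.
    """
    for name, pos in (p, q):
        if name not in cs.lengths:
            raise InvalidInputError(f"unknown sequence {name!r}")
        if not 0 <= pos < cs.lengths[name]:
            raise InvalidInputError(f"position {pos} out of range in {name!r}")
    if p == q:
        return "equal"
    poset = cs.poset
    cls_p, cls_q = poset.class_of.get(p), poset.class_of.get(q)
    if cls_p is not None and cls_p == cls_q:
        return "equal"
    if p[0] == q[0]:
        return "before" if p[1] < q[1] else "after"
    up = poset.upper_bounds(p)[q[0]]
    if up is not None and up <= q[1]:
        return "before"
    down = poset.lower_bounds(p)[q[0]]
    if down is not None and down >= q[1]:
        return "after"
    return "incomparable"


# ---------------------------------------------------------------------------
# Anchor-based constraint generation
# ---------------------------------------------------------------------------


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        counts[seq[i : i + k]] = counts.get(seq[i : i + k], 0) + 1
    return {
        seq[i : i + k]: i
        for i in range(len(seq) - k + 1)
        if counts[seq[i : i + k]] == 1
    }


def _chain_anchors(
    anchors: list[tuple[int, int]], k: int, cap: Optional[int]
) -> list[tuple[int, int, int]]:
    """Maximal non-crossing chain of anchor runs, as (a, b, length) triples.

    Anchors on one diagonal that overlap or abut merge into runs first;
    runs are then chained to a maximum-coverage non-overlapping subset
    (weighted longest increasing subsequence, O(n^2))."""
    if not anchors:
        return []
    by_diag: dict[int, list[int]] = {}
    for a, b in anchors:
        by_diag.setdefault(b - a, []).append(a)
    runs: list[tuple[int, int, int]] = []
    for diag, starts in by_diag.items():
        starts.sort()
        run_start, run_end = starts[0], starts[0] + k
        for a in starts[1:]:
            if a <= run_end:
                run_end = max(run_end, a + k)
            else:
                runs.append((run_start, run_start + diag, run_end - run_start))
                run_start, run_end = a, a + k
        runs.append((run_start, run_start + diag, run_end - run_start))
    runs.sort()
    n = len(runs)
    best = [r[2] for r in runs]
    prev = [-1] * n
    for i in range(n):
        ai, bi, li = runs[i]
        for j in range(i):
            aj, bj, lj = runs[j]
            if aj + lj <= ai and bj + lj <= bi and best[j] + li > best[i]:
                best[i] = best[j] + li
                prev[i] = j
    end = max(range(n), key=lambda i: (best[i], -runs[i][0]))
    chain = []
    while end != -1:
        chain.append(runs[end])
        end = prev[end]
    chain.reverse()
    if cap is not None and len(chain) > cap:
        # keep an evenly spaced subset, deterministic
        step = len(chain) / cap
        chain = [chain[int(i * step)] for i in range(cap)]
    return chain


def generate_anchor_constraints(
    seqs: Sequence[SequenceRecord],
    k: int,
    max_anchors_per_pair: Optional[int] = None,
) -> ConstraintSet:
    """Exact-match k-mer anchors chained pairwise and expanded to per-base
    constraints.

    For each sequence pair, k-mers unique within both sequences and exact
    between them (N matches only N) are chained to a maximal non-crossing
    subset and expanded base by base. Constraints that are globally
    inconsistent across pairs are greedily dropped (lexicographically
    first constraint on each detected cycle) until the set is a partial
    order.
    """
    if k < 4:
        raise InvalidInputError("k must be >= 4")
    if len(seqs) < 2:
        raise InvalidInputError("need at least 2 sequences")
    uniq = {s.name: _unique_kmers(s.residues, k) for s in seqs}
    constraints: set[Constraint] = set()
    names = [s.name for s in seqs]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            shared = set(uniq[a]) & set(uniq[b])
            anchors = [(uniq[a][m], uniq[b][m]) for m in shared]
            for pa, pb, run_len in _chain_anchors(anchors, k, max_anchors_per_pair):
                for off in range(run_len):
                    constraints.add(Constraint.make(a, pa + off, b, pb + off))
    cs = ConstraintSet(seqs, constraints)
    while True:
        ok, violating = check_consistency(cs)
        if ok:
            return cs
        # greedy repair: drop the lexicographically first implicated
        # constraint, then re-check (documented deterministic rule)
        drop = violating[0]
        cs = cs.replace_constraints(cs.constraints - {drop})


# ---------------------------------------------------------------------------
# Constraint TSV dialect: `seq_a \t pos_a \t seq_b \t pos_b`, '#' comments
# ---------------------------------------------------------------------------


def read_constraints_tsv(path, sequences: Sequence[SequenceRecord]) -> ConstraintSet:
    constraints = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise InvalidInputError(
                    f"{path}:{lineno}: expected 4 tab-separated fields"
                )
            try:
                constraints.append(
                    Constraint.make(parts[0], int(parts[1]), parts[2], int(parts[3]))
                )
            except ValueError as exc:
                raise InvalidInputError(f"{path}:{lineno}: {exc}") from exc
    return ConstraintSet(sequences, constraints)


def write_constraints_tsv(cs: ConstraintSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("# seq_a\tpos_a\tseq_b\tpos_b\n")
        for c in sorted(cs.constraints):
            fh.write(f"{c.seq_a}\t{c.pos_a}\t{c.seq_b}\t{c.pos_b}\n")
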