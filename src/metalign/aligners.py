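"""Aligner backends.

The partitioning methods in this package never align sequences
themselves — they delegate to a pluggable *backend* and reassemble the
results. The contract is small: a backend maps a list of sequence
records (plus an optional guide tree) to a multiple alignment whose rows
project exactly back onto the inputs. A deterministic built-in backend
is provided so the whole package runs without external binaries, and a
wrapper turns any command-line global aligner into a backend.

The built-in aligner is progressive: it walks the guide tree from the
leaves up and, at each internal node, pairwise-aligns one representative
leaf sequence from each side (the leaf nearest the node by branch
length) with affine-gap global dynamic programming, then expands the two
child sub-alignments through the representatives as guide rows. Merging
through leaf guides, rather than profile columns, is what makes the
depth-wise partitioner's two-sequences-per-subtree mode reduce to this
aligner exactly.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import BackendError, InvalidInputError
from .merge import merge_alignments
from .msa import GAP, MultipleAlignment, SequenceRecord
from .tree import PhyloTree, TreeNode

NEG_INF = float(-1e18)


@dataclass(frozen=True)
class AlignmentParams:
    """Scores under a maximisation convention; gap penalties are <= 0."""

    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise InvalidInputError("gap penalties must be <= 0")


DEFAULT_PARAMS = AlignmentParams()


def pairwise_align(
    a: str, b: str, params: AlignmentParams = DEFAULT_PARAMS
) -> tuple[str, str, float]:
    """Global affine-gap alignment of two sequences (Gotoh, three states).

    Returns the two gapped rows and the optimal score. Ties are broken
    deterministically: diagonal (match state) first, then a gap in the
    second sequence (up), then a gap in the first (left); within a gap
    state, closing the gap (coming from the match state) is preferred.
    """
    n, m = len(a), len(b)
    go, ge = float(params.gap_open), float(params.gap_extend)
    if n == 0 or m == 0:
        score = 0.0 if n == m == 0 else go + ge * (n + m - 1)
        return a + GAP * m, GAP * n + b, score

    codes = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
    ai = np.array([codes[c] for c in a], dtype=np.int8)
    bi = np.array([codes[c] for c in b], dtype=np.int8)

    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)  # gap in b (consumes a; "up")
    Y = np.full((n + 1, m + 1), NEG_INF)  # gap in a (consumes b; "left")
    M[0, 0] = 0.0
    X[1:, 0] = go + ge * np.arange(n)
    Y[0, 1:] = go + ge * np.arange(m)

    jj = np.arange(m)
    for i in range(1, n + 1):
        sub = np.where(bi == ai[i - 1], params.match, params.mismatch).astype(float)
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + sub
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) + go, X[i - 1, 1:] + ge
        )
        X[i, 0] = max(M[i - 1, 0] + go, X[i - 1, 0] + ge)
        # Y along the row: a horizontal gap run opened after column k has
        # score best(M, X)[i, k] + go + ge*(j - k - 1); a running maximum
        # over k gives the whole row in one accumulate pass.
        z = np.maximum(M[i, :-1], X[i, :-1]) + go - ge * (jj + 1)
        Y[i, 1:] = ge * (jj + 1) + np.maximum.accumulate(z)

    # traceback; preferences resolve exact float ties (integer arithmetic)
    rows_a: list[str] = []
    rows_b: list[str] = []
    i, j = n, m
    state = max(
        (("M", M[n, m]), ("X", X[n, m]), ("Y", Y[n, m])),
        key=lambda kv: (kv[1], {"M": 2, "X": 1, "Y": 0}[kv[0]]),
    )[0]
    score = {"M": M[n, m], "X": X[n, m], "Y": Y[n, m]}[state]
    while i > 0 or j > 0:
        if state == "M":
            rows_a.append(a[i - 1])
            rows_b.append(b[j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = max(
                (("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])),
                key=lambda kv: (kv[1], {"M": 2, "X": 1, "Y": 0}[kv[0]]),
            )[0]
        elif state == "X":
            rows_a.append(a[i - 1])
            rows_b.append(GAP)
            target = X[i, j]
            i -= 1
            if target == M[i, j] + go:
                state = "M"
            elif target == X[i, j] + ge:
                state = "X"
            else:
                state = "Y"
        else:
            rows_a.append(GAP)
            rows_b.append(b[j - 1])
            target = Y[i, j]
            j -= 1
            if target == M[i, j] + go:
                state = "M"
            elif target == X[i, j] + go:
                state = "X"
            else:
                state = "Y"
    return "".join(reversed(rows_a)), "".join(reversed(rows_b)), float(score)


# ---------------------------------------------------------------------------
# Guide trees: neighbour joining on a shared-k-mer distance
# ---------------------------------------------------------------------------


def kmer_distance(a: str, b: str, k: int = 6) -> float:
    """1 minus the shared fraction of k-mer sets (normalised by the smaller set)."""
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    denom = min(len(ka), len(kb))
    if denom == 0:
        return 1.0
    return 1.0 - len(ka & kb) / denom


def nj_guide_tree(seqs: Sequence[SequenceRecord], k: int = 6) -> PhyloTree:
    """Neighbour joining with deterministic, name-based tie-breaking."""
    if not seqs:
        raise InvalidInputError("cannot build a guide tree for zero sequences")
    if len(seqs) == 1:
        return PhyloTree(TreeNode(name=seqs[0].name))
    # cluster key = sorted tuple of leaf names (deterministic identity)
    nodes: dict[tuple[str, ...], TreeNode] = {
        (s.name,): TreeNode(name=s.name) for s in seqs
    }
    dist: dict[frozenset[tuple[str, ...]], float] = {}
    keys = sorted(nodes)
    for x in range(len(keys)):
        for y in range(x + 1, len(keys)):
            a, b = keys[x], keys[y]
            sa = next(s for s in seqs if s.name == a[0])
            sb = next(s for s in seqs if s.name == b[0])
            dist[frozenset((a, b))] = kmer_distance(sa.residues, sb.residues, k)

    def d(a, b):
        return dist[frozenset((a, b))]

    while len(nodes) > 2:
        keys = sorted(nodes)
        r = len(keys)
        totals = {a: sum(d(a, b) for b in keys if b != a) for a in keys}
        best = None
        for x in range(r):
            for y in range(x + 1, r):
                a, b = keys[x], keys[y]
                q = (r - 2) * d(a, b) - totals[a] - totals[b]
                cand = (q, a, b)
                if best is None or cand < best:
                    best = cand
        _, a, b = best
        la = 0.5 * d(a, b) + (totals[a] - totals[b]) / (2 * (r - 2))
        lb = d(a, b) - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        merged_key = tuple(sorted(a + b))
        left_key, right_key = sorted((a, b))
        nodes[left_key].length = la if left_key == a else lb
        nodes[right_key].length = lb if right_key == b else la
        merged = TreeNode(left=nodes[left_key], right=nodes[right_key])
        new_d = {}
        for c in keys:
            if c in (a, b):
                continue
            new_d[c] = 0.5 * (d(a, c) + d(b, c) - d(a, b))
        del nodes[a], nodes[b]
        for key in list(dist):
            if key & {a, b}:
                del dist[key]
        for c, v in new_d.items():
            dist[frozenset((merged_key, c))] = max(v, 0.0)
        nodes[merged_key] = merged
    (ka, na), (kb, nb) = sorted(nodes.items())
    half = max(d(ka, kb) / 2.0, 0.0)
    na.length = half
    nb.length = half
    return PhyloTree(TreeNode(left=na, right=nb))


# ---------------------------------------------------------------------------
# Progressive alignment
# ---------------------------------------------------------------------------


def nearest_leaf_below(tree: PhyloTree, node: TreeNode) -> tuple[str, float]:
    """Leaf below ``node`` with minimal branch-length distance to it.

    Ties break on the leaf name.
    """
    if node.is_leaf:
        return node.name, 0.0  # type: ignore[return-value]
    best: Optional[tuple[float, str]] = None
    for child in node.children():
        name, dist = nearest_leaf_below(tree, child)
        cand = (dist + child.length, name)
        if best is None or cand < best:
            best = cand
    return best[1], best[0]


def _guide_map(row: str) -> list[int]:
    return [j for j, ch in enumerate(row) if ch != GAP]


def progressive_align(
    seqs: Sequence[SequenceRecord],
    guide_tree: Optional[PhyloTree] = None,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> MultipleAlignment:
    """Progressive multiple alignment over a guide tree.

    Sibling sub-alignments merge through a pairwise alignment of their
    representative leaves (nearest to the merge node by branch length).
    Without a guide tree, one is built by neighbour joining on k-mer
    distances. Rows are returned in input order.
    """
    if len(seqs) == 0:
        return MultipleAlignment([], [])
    by_name = {s.name: s for s in seqs}
    if len(by_name) != len(seqs):
        raise InvalidInputError("duplicate sequence names")
    if len(seqs) == 1:
        return MultipleAlignment.from_records(seqs)
    if guide_tree is None:
        guide_tree = nj_guide_tree(seqs)
    tree_names = set(guide_tree.leaf_names())
    if tree_names != set(by_name):
        raise InvalidInputError("guide tree leaves do not match sequence names")

    def build(node: TreeNode) -> tuple[MultipleAlignment, str]:
        """Returns (alignment over leaves below node, representative leaf)."""
        if node.is_leaf:
            rec = by_name[node.name]  # type: ignore[index]
            return MultipleAlignment([rec.name], [rec.residues]), rec.name
        left_aln, _ = build(node.left)
        right_aln, _ = build(node.right)
        rep_l, _ = nearest_leaf_below(guide_tree, node.left)
        rep_r, _ = nearest_leaf_below(guide_tree, node.right)
        row_l, row_r, _score = pairwise_align(
            by_name[rep_l].residues, by_name[rep_r].residues, params
        )
        parent = MultipleAlignment([rep_l, rep_r], [row_l, row_r], validate=False)
        merged, _ = merge_alignments(
            parent,
            {
                rep_l: (left_aln, _guide_map(left_aln.row(rep_l))),
                rep_r: (right_aln, _guide_map(right_aln.row(rep_r))),
            },
        )
        rep, _ = nearest_leaf_below(guide_tree, node)
        return merged, rep

    aln, _ = build(guide_tree.root)
    return aln.reorder([s.name for s in seqs])


# ---------------------------------------------------------------------------
# Backend contract
# ---------------------------------------------------------------------------


class AlignerBackend:
    """Base class enforcing the backend contract on every result.

    Subclasses implement :meth:`_align`. Results are validated (rows must
    project to the inputs), stripped of all-gap columns, and reordered to
    the input order. A single sequence is returned unchanged without
    invoking the backend.
    """

    name = "backend"

    def align(
        self,
        seqs: Sequence[SequenceRecord],
        guide_tree: Optional[PhyloTree] = None,
    ) -> MultipleAlignment:
        seqs = list(seqs)
        if len(seqs) == 0:
            return MultipleAlignment([], [])
        if len(seqs) == 1:
            return MultipleAlignment.from_records(seqs)
        raw = self._align(seqs, guide_tree)
        expected = {s.name: s.residues for s in seqs}
        if set(raw.names) != set(expected):
            raise BackendError(
                f"{self.name}: output rows {sorted(raw.names)} do not match "
                f"input names {sorted(expected)}"
            )
        for name in raw.names:
            if raw.projection(name) != expected[name]:
                raise BackendError(
                    f"{self.name}: row {name!r} does not project to its input "
                    "sequence (projection violation)"
                )
        return raw.drop_all_gap_columns().reorder([s.name for s in seqs])

    def _align(
        self,
        seqs: Sequence[SequenceRecord],
        guide_tree: Optional[PhyloTree],
    ) -> MultipleAlignment:
        raise NotImplementedError


class BuiltinAligner(AlignerBackend):
    """The deterministic built-in progressive aligner."""

    name = "builtin"

    def __init__(self, params: AlignmentParams = DEFAULT_PARAMS) -> None:
        self.params = params

    def _align(self, seqs, guide_tree):
        return progressive_align(seqs, guide_tree, self.params)


class ExternalAligner(AlignerBackend):
    """Wrap a command-line global aligner.

    The command template must contain ``{in}`` and ``{out}`` placeholders
    for the unaligned input FASTA and the aligned output FASTA.
    """

    def __init__(self, command_template: str) -> None:
        if "{in}" not in command_template or "{out}" not in command_template:
            raise InvalidInputError(
                "command template must contain {in} and {out} placeholders"
            )
        self.template = command_template
        self.name = f"cmd:{command_template}"

    def _align(self, seqs, guide_tree):
        from .io import read_alignment, write_fasta

        with tempfile.TemporaryDirectory(prefix="metalign_ext_") as tmp:
            fa_in = Path(tmp) / "in.fa"
            fa_out = Path(tmp) / "out.fa"
            write_fasta(seqs, fa_in)
            cmd = self.template.replace("{in}", str(fa_in)).replace(
                "{out}", str(fa_out)
            )
            proc = subprocess.run(
                cmd, shell=True, capture_output=True, text=True
            )
            if proc.returncode != 0:
                raise BackendError(
                    f"external aligner failed (exit {proc.returncode}): "
                    f"{cmd}\nstderr: {proc.stderr[-2000:]}"
                )
            if not fa_out.exists():
                raise BackendError(f"external aligner produced no output: {cmd}")
            try:
                return read_alignment(fa_out)
            except Exception as exc:
                raise BackendError(
                    f"external aligner output unparseable: {exc}"
                ) from exc


def backend_from_spec(spec: str, params: AlignmentParams = DEFAULT_PARAMS) -> AlignerBackend:
    """``builtin`` or ``cmd:<template with {in}/{out}>``."""
    if spec == "builtin":
        return BuiltinAligner(params)
    if spec.startswith("cmd:"):
        return ExternalAligner(spec[4:])
    raise InvalidInputError(f"unknown backend spec {spec!r}")
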