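"""Depth-wise partitioning of a phylogenetic alignment problem.

A rooted binary tree is cut into sub-trees that overlap at internal
*cut* nodes. Each sub-tree problem aligns its *frontier* — the leaf
sequences and inferred root sequences of child sub-trees that it
actually sees — plus an optional out-group leaf for context. Sub-trees
are chosen by dynamic programming to minimise the number of sequential
*stages* (a stage is a set of sub-tree problems that can run
concurrently) subject to a cap ``M`` on frontier size. After all
sub-tree alignments exist, they are merged bottom-up through the
inferred root sequences acting as guide rows.

Stage bookkeeping counts the trivial single-sequence "alignment" of a
leaf as stage 1, so a single sub-tree spanning the whole tree completes
at stage 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

from .aligners import AlignerBackend
from .errors import InfeasibleError, InvalidInputError
from .executor import ExecutorConfig, Job
from .merge import merge_alignments
from .msa import GAP, MultipleAlignment, SequenceRecord
from .tree import PhyloTree, TreeNode

# a frontier member is either a leaf name or the root of a child sub-tree
Member = tuple[Literal["leaf", "root"], object]

INF = math.inf


@dataclass
class SubTreeProblem:
    """One sub-tree alignment problem of a decomposition."""

    root_id: int
    frontier: list[Member]  # post-order over the sub-tree
    stage: int
    out_group: Optional[str] = None

    @property
    def n_frontier(self) -> int:
        return len(self.frontier)


@dataclass
class Decomposition:
    problems: list[SubTreeProblem]
    stage_count: int

    def by_root(self) -> dict[int, SubTreeProblem]:
        return {p.root_id: p for p in self.problems}


def min_stage_count(tree: PhyloTree, M: int) -> int:
    """Minimum number of sequential stages under frontier cap ``M``.

    Runs the recurrence only (no backtracking); linear in the leaf count
    for fixed ``M``.
    """
    return _stage_tables(tree, M)[0]


def _stage_tables(tree: PhyloTree, M: int):
    """DP tables. T[node_id][j] = min stages if the sub-tree below the node
    contributes exactly j sequences to its enclosing problem; j = 1 means
    the node is a cut node (or a leaf). choice[(id, j)] = (j_left, j_right).
    """
    if M < 2:
        raise InfeasibleError("maximum sub-tree size M must be >= 2")
    T: dict[int, list[float]] = {}
    choice: dict[tuple[int, int], tuple[int, int]] = {}
    for node in tree.postorder():
        row = [INF] * (M + 1)  # index j, 1..M
        if node.is_leaf:
            row[1] = 1.0
        else:
            tl, tr = T[node.left.node_id], T[node.right.node_id]
            # node inside the enclosing problem: split j between children
            for j in range(2, M + 1):
                best, arg = INF, None
                for jl in range(1, j):
                    jr = j - jl
                    val = max(tl[jl], tr[jr])
                    if val < best:
                        best, arg = val, (jl, jr)
                row[j] = best
                if arg is not None:
                    choice[(node.node_id, j)] = arg
            # node as a cut node: its own problem merges the children
            best, arg = INF, None
            for jl in range(1, M):
                for jr in range(1, M + 1 - jl):
                    val = max(tl[jl], tr[jr])
                    if val < best:
                        best, arg = val, (jl, jr)
            row[1] = best + 1.0
            choice[(node.node_id, 1)] = arg
        T[node.node_id] = row
    total = T[tree.root.node_id][1]
    if not math.isfinite(total):
        raise InfeasibleError(f"no decomposition exists for M={M}")
    return int(total), T, choice


def min_stage_decomposition(tree: PhyloTree, M: int) -> Decomposition:
    """A decomposition achieving the minimum stage count.

    Ties in the recurrence break deterministically toward the smallest
    left-child share, so the result is reproducible.
    """
    total, T, choice = _stage_tables(tree, M)
    problems: list[SubTreeProblem] = []

    def collect(node: TreeNode, j: int) -> list[Member]:
        """Frontier members contributed by ``node`` inside an enclosing
        problem, when it accounts for j sequences."""
        if node.is_leaf:
            return [("leaf", node.name)]
        if j == 1:
            cut(node)
            return [("root", node.node_id)]
        jl, jr = choice[(node.node_id, j)]
        return collect(node.left, jl) + collect(node.right, jr)

    def cut(node: TreeNode) -> None:
        """Emit the sub-tree problem rooted at this cut node."""
        if node.is_leaf:
            return  # trivial single-sequence stage; not a problem
        jl, jr = choice[(node.node_id, 1)]
        frontier = collect(node.left, jl) + collect(node.right, jr)
        problems.append(
            SubTreeProblem(
                root_id=node.node_id,
                frontier=frontier,
                stage=int(T[node.node_id][1]),
            )
        )

    cut(tree.root)
    problems.sort(key=lambda p: (p.stage, p.root_id))
    return Decomposition(problems=problems, stage_count=total)


# ---------------------------------------------------------------------------
# Root inference
# ---------------------------------------------------------------------------

_BASE_ORDER = "ACGTN"  # deterministic tie-break order


def infer_root_maximal(aln: MultipleAlignment) -> str:
    """Most frequent non-gap base per column (ties: A < C < G < T < N).

    Infers the longest root sequence that fits within the alignment: one
    base for every column.
    """
    if aln.n_rows < 1:
        raise InvalidInputError("cannot infer a root from an empty alignment")
    out = []
    for j in range(aln.n_cols):
        col = aln.column(j)
        counts = {b: 0 for b in _BASE_ORDER}
        for ch in col:
            if ch != GAP:
                counts[ch] += 1
        best = max(_BASE_ORDER, key=lambda b: (counts[b], -_BASE_ORDER.index(b)))
        if counts[best] == 0:
            raise InvalidInputError(f"all-gap column {j} in alignment")
        out.append(best)
    return "".join(out)


@dataclass(frozen=True)
class InferredRoot:
    """An inferred root sequence plus its anchoring in the sub-alignment.

    ``col_map[r]`` is the column of the sub-tree alignment that residue
    ``r`` of the inferred sequence occupies; ``source_leaf`` names the
    leaf the sequence was copied from, when the method selects a leaf.
    """

    sequence: str
    col_map: tuple[int, ...]
    source_leaf: Optional[str] = None


@dataclass
class InferenceContext:
    """What a root-inference method may consult besides the alignment."""

    tree: PhyloTree
    root_node: TreeNode
    trace: dict[str, str]  # row name -> underlying leaf name


class RootInferenceMethod:
    name = "abstract"

    def infer(self, aln: MultipleAlignment, ctx: InferenceContext) -> InferredRoot:
        raise NotImplementedError


class MaximalInference(RootInferenceMethod):
    """Column-consensus root: one base per column (bijective guide map)."""

    name = "maximal"

    def infer(self, aln: MultipleAlignment, ctx: InferenceContext) -> InferredRoot:
        seq = infer_root_maximal(aln)
        return InferredRoot(seq, tuple(range(aln.n_cols)))


class NearestLeafInference(RootInferenceMethod):
    """Copy the row whose underlying leaf is nearest the sub-tree root.

    Distance is the branch-length path in the full tree; ties break on
    the leaf name. The guide map is injective but generally not
    surjective, so merging may need to re-insert unmapped columns.
    """

    name = "nearest-leaf"

    def infer(self, aln: MultipleAlignment, ctx: InferenceContext) -> InferredRoot:
        best = None
        for row_name in aln.names:
            leaf_name = ctx.trace[row_name]
            dist = ctx.tree.path_length(ctx.tree.leaf(leaf_name), ctx.root_node)
            cand = (dist, leaf_name, row_name)
            if best is None or cand < best:
                best = cand
        _, leaf_name, row_name = best
        row = aln.row(row_name)
        cmap = tuple(j for j, ch in enumerate(row) if ch != GAP)
        return InferredRoot(row.replace(GAP, ""), cmap, source_leaf=leaf_name)


def get_inference(name: str) -> RootInferenceMethod:
    methods = {"maximal": MaximalInference, "nearest-leaf": NearestLeafInference}
    try:
        return methods[name]()
    except KeyError:
        raise InvalidInputError(f"unknown inference method {name!r}") from None


# ---------------------------------------------------------------------------
# Out-groups
# ---------------------------------------------------------------------------


def select_outgroup(tree: PhyloTree, sub_root_id: int) -> Optional[str]:
    """Leaf outside the sub-tree nearest its root by branch length.

    Returns None when the sub-tree is the whole tree. Ties break on the
    leaf name.
    """
    sub_root = tree.node(sub_root_id)
    inside = set(tree.leaf_names(sub_root))
    best = None
    for leaf in tree.leaves():
        if leaf.name in inside:
            continue
        cand = (tree.path_length(leaf, sub_root), leaf.name)
        if best is None or cand < best:
            best = cand
    return best[1] if best is not None else None


# ---------------------------------------------------------------------------
# The Prune pipeline
# ---------------------------------------------------------------------------


def _root_row_name(node_id: int) -> str:
    return f"#root{node_id}"


def _induced_guide_tree(
    tree: PhyloTree, problem: SubTreeProblem
) -> PhyloTree:
    """The sub-tree rooted at the problem's root, truncated at cut nodes
    (which become leaves named after their inferred root rows)."""
    cut_ids = {m[1] for m in problem.frontier if m[0] == "root"}

    def clone(node: TreeNode, is_root: bool) -> TreeNode:
        length = 0.0 if is_root else node.length
        if not is_root and node.node_id in cut_ids:
            return TreeNode(name=_root_row_name(node.node_id), length=length)
        if node.is_leaf:
            return TreeNode(name=node.name, length=length)
        return TreeNode(
            left=clone(node.left, False),
            right=clone(node.right, False),
            length=length,
        )

    return PhyloTree(clone(tree.node(problem.root_id), True))


def prune_align(
    seqs: Sequence[SequenceRecord],
    tree: PhyloTree,
    M: int,
    backend: AlignerBackend,
    inference: Optional[RootInferenceMethod] = None,
    use_outgroups: bool = False,
    executor: Optional[ExecutorConfig] = None,
) -> MultipleAlignment:
    """Align ``seqs`` over ``tree`` via minimum-stage sub-tree problems.

    Sub-tree problems of the same stage run as parallel child jobs; each
    problem aligns its frontier (plus out-group when enabled — the
    out-group row is dropped right after alignment), infers its root, and
    hands the inferred sequence to its parent's problem. The final
    alignment is the bottom-up merge of all sub-alignments through the
    inferred roots; rows come back in input order and project exactly to
    the input sequences.
    """
    if inference is None:
        inference = MaximalInference()
    if executor is None:
        executor = ExecutorConfig(jobs=1)
    seqs = list(seqs)
    by_name = {s.name: s for s in seqs}
    leaf_names = set(tree.leaf_names())
    missing = leaf_names - set(by_name)
    if missing:
        raise InvalidInputError(f"missing sequences for leaves: {sorted(missing)}")
    if set(by_name) - leaf_names:
        raise InvalidInputError("sequences present that are not leaves of the tree")
    if not seqs:
        return MultipleAlignment([], [])
    if len(seqs) == 1:
        return MultipleAlignment.from_records(seqs)

    decomp = min_stage_decomposition(tree, M)
    by_root = decomp.by_root()
    whole_tree_root = tree.root.node_id

    aligned: dict[int, MultipleAlignment] = {}
    inferred: dict[int, InferredRoot] = {}
    trace: dict[str, str] = {s.name: s.name for s in seqs}

    def solve(problem: SubTreeProblem) -> None:
        records: list[SequenceRecord] = []
        for kind, ref in problem.frontier:
            if kind == "leaf":
                records.append(by_name[ref])
            else:
                name = _root_row_name(ref)
                records.append(SequenceRecord(name, inferred[ref].sequence))
        guide = _induced_guide_tree(tree, problem)
        out_group = None
        if use_outgroups and problem.root_id != whole_tree_root:
            out_group = select_outgroup(tree, problem.root_id)
            if out_group is not None and out_group not in {r.name for r in records}:
                og_len = tree.path_length(
                    tree.leaf(out_group), tree.node(problem.root_id)
                )
                guide = PhyloTree(
                    TreeNode(
                        left=guide.copy().root,
                        right=TreeNode(name=out_group, length=og_len),
                    )
                )
                records = records + [by_name[out_group]]
            else:
                out_group = None
        problem.out_group = out_group
        aln = backend.align(records, guide)
        if out_group is not None:
            keep = [n for n in aln.names if n != out_group]
            aln = aln.subset(keep)
        ctx = InferenceContext(
            tree=tree, root_node=tree.node(problem.root_id), trace=trace
        )
        root = inference.infer(aln, ctx)
        aligned[problem.root_id] = aln
        inferred[problem.root_id] = root
        trace[_root_row_name(problem.root_id)] = (
            root.source_leaf if root.source_leaf is not None
            else _root_row_name(problem.root_id)
        )

    # schedule: one job per problem, grouped into stage jobs chained by
    # follow-ons; same-stage problems are independent children
    stages = sorted({p.stage for p in decomp.problems})
    stage_jobs = [Job(f"stage-{s}") for s in stages]
    for job, s in zip(stage_jobs, stages):
        for problem in decomp.problems:
            if problem.stage == s:
                job.add_child(
                    Job(
                        f"subtree-{problem.root_id}",
                        action=lambda _j, p=problem: solve(p),
                    )
                )
    for a, b in zip(stage_jobs, stage_jobs[1:]):
        a.set_follow_on(b)
    executor.run(stage_jobs[0])

    def expand(problem: SubTreeProblem) -> tuple[MultipleAlignment, list[int]]:
        guides = {}
        for kind, ref in problem.frontier:
            if kind != "root":
                continue
            child_aln, child_map = expand(by_root[ref])
            root = inferred[ref]
            if root.source_leaf is not None:
                row = child_aln.row(root.source_leaf)
                cmap = [j for j, ch in enumerate(row) if ch != GAP]
            else:
                cmap = [child_map[j] for j in root.col_map]
            guides[_root_row_name(ref)] = (child_aln, cmap)
        if not guides:
            return aligned[problem.root_id], list(range(aligned[problem.root_id].n_cols))
        return merge_alignments(aligned[problem.root_id], guides)

    final, _ = expand(by_root[whole_tree_root])
    final = final.reorder([s.name for s in seqs])
    final.check_projection({s.name: s.residues for s in seqs})
    return final
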