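"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's own algorithms: reachability via
breadth-first search over the full position graph, decompositions by
exhaustive enumeration of cut sets, pairwise alignment by exhaustive
path enumeration, and merging by naive column-by-column rebuilding.
"""

from __future__ import annotations

import itertools
from typing import Optional

import networkx as nx

from metalign import ConstraintSet, MultipleAlignment
from metalign.tree import PhyloTree, TreeNode


# ---------------------------------------------------------------------------
# position-order oracle: BFS over the complete position graph
# ---------------------------------------------------------------------------


class PositionOrderOracle:
    """Reachability over all positions: equality classes by union of aligned
    pairs, plus every within-sequence adjacency edge."""

    def __init__(self, cs: ConstraintSet):
        parent: dict = {}

        def find(x):
            while parent.get(x, x) != x:
                x = parent[x]
            return x

        for c in cs.constraints:
            p, q = c.positions()
            rp, rq = find(p), find(q)
            if rp != rq:
                parent[max(rp, rq)] = min(rp, rq)
        self.find = find
        g = nx.DiGraph()
        for s in cs.sequences:
            for i in range(len(s)):
                g.add_node(find((s.name, i)))
            for i in range(len(s) - 1):
                g.add_edge(find((s.name, i)), find((s.name, i + 1)))
        self.reach = {
            node: set(nx.descendants(g, node)) | {node} for node in g.nodes
        }
        self.cs = cs

    def leq(self, p, q) -> bool:
        return self.find(q) in self.reach[self.find(p)]

    def order(self, p, q) -> str:
        le, ge = self.leq(p, q), self.leq(q, p)
        if le and ge:
            return "equal"
        if le:
            return "before"
        if ge:
            return "after"
        return "incomparable"

    def least_upper_bounds(self, anchor) -> dict[str, Optional[int]]:
        out = {}
        for s in self.cs.sequences:
            out[s.name] = next(
                (i for i in range(len(s)) if self.leq(anchor, (s.name, i))), None
            )
        return out

    def greatest_lower_bounds(self, anchor) -> dict[str, Optional[int]]:
        out = {}
        for s in self.cs.sequences:
            out[s.name] = next(
                (i for i in reversed(range(len(s))) if self.leq((s.name, i), anchor)),
                None,
            )
        return out

    def is_consistent(self) -> bool:
        for s in self.cs.sequences:
            for i in range(len(s)):
                for j in range(i + 1, len(s)):
                    if self.leq((s.name, j), (s.name, i)):
                        return False
        return True


# ---------------------------------------------------------------------------
# decomposition oracle: exhaustive enumeration over cut sets
# ---------------------------------------------------------------------------


def min_stages_exhaustive(tree: PhyloTree, M: int) -> Optional[int]:
    """Minimum stage count over ALL valid decompositions, by enumerating
    every subset of internal nodes as cut nodes (the root is always cut).

    Stage semantics: a leaf completes at stage 1; a sub-tree problem
    completes one stage after the latest of its frontier members.
    Returns None when no decomposition satisfies the frontier cap.
    """
    internals = [n for n in tree.postorder() if not n.is_leaf]
    optional = [n for n in internals if n is not tree.root]
    best: Optional[int] = None
    for r in range(len(optional) + 1):
        for combo in itertools.combinations(optional, r):
            cuts = {n.node_id for n in combo} | {tree.root.node_id}
            stage: dict[int, int] = {}
            feasible = True

            def frontier(node: TreeNode) -> list[TreeNode]:
                members = []
                for child in node.children():
                    if child.is_leaf or child.node_id in cuts:
                        members.append(child)
                    else:
                        members.extend(frontier(child))
                return members

            for node in tree.postorder():
                if node.is_leaf:
                    stage[node.node_id] = 1
                elif node.node_id in cuts:
                    members = frontier(node)
                    if len(members) > M:
                        feasible = False
                        break
                    stage[node.node_id] = 1 + max(
                        stage[m.node_id] for m in members
                    )
            if feasible:
                total = stage[tree.root.node_id]
                if best is None or total < best:
                    best = total
    return best


def all_tree_shapes(n: int) -> list[PhyloTree]:
    """All rooted binary tree shapes with n leaves (canonical labelled
    representatives; the stage recurrence is label-invariant)."""

    def shapes(k: int) -> list[TreeNode]:
        if k == 1:
            return [TreeNode()]
        out = []
        seen = set()
        for left_k in range(1, k // 2 + 1):
            for left in shapes(left_k):
                for right in shapes(k - left_k):
                    node = TreeNode(left=_clone(left), right=_clone(right))
                    key = _shape_key(node)
                    if key not in seen:
                        seen.add(key)
                        out.append(node)
        return out

    def _clone(node: TreeNode) -> TreeNode:
        return TreeNode(
            left=_clone(node.left) if node.left else None,
            right=_clone(node.right) if node.right else None,
        )

    def _shape_key(node: TreeNode) -> str:
        if node.left is None:
            return "*"
        kids = sorted([_shape_key(node.left), _shape_key(node.right)])
        return f"({kids[0]},{kids[1]})"

    trees = []
    for root in shapes(n):
        counter = itertools.count(1)
        for leaf in _leaves(root):
            leaf.name = f"L{next(counter)}"
        for node in _all(root):
            node.length = 1.0
        root.length = 0.0
        trees.append(PhyloTree(root))
    return trees


def _leaves(node: TreeNode):
    if node.left is None:
        yield node
    else:
        yield from _leaves(node.left)
        yield from _leaves(node.right)


def _all(node: TreeNode):
    yield node
    if node.left is not None:
        yield from _all(node.left)
        yield from _all(node.right)


# ---------------------------------------------------------------------------
# pairwise alignment score oracle: exhaustive path enumeration
# ---------------------------------------------------------------------------


def best_affine_score_exhaustive(a: str, b: str, match, mismatch, open_, extend) -> float:
    """Optimal affine-gap global alignment score by enumerating every
    alignment path recursively (no dynamic programming)."""

    best = [float("-inf")]

    def go(i: int, j: int, score: float, last: str) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            go(i + 1, j + 1, score + s, "m")
        if i < len(a):
            gap = extend if last == "x" else open_
            go(i + 1, j, score + gap, "x")
        if j < len(b):
            gap = extend if last == "y" else open_
            go(i, j + 1, score + gap, "y")

    go(0, 0, 0.0, "m")
    return best[0]


# ---------------------------------------------------------------------------
# alignment comparison helpers
# ---------------------------------------------------------------------------


def aligned_pairs(aln: MultipleAlignment) -> set[tuple]:
    """All residue–residue homologies implied by an alignment, as
    ((name_a, idx_a), (name_b, idx_b)) with name_a < name_b."""
    out = set()
    names = aln.names
    counters = {n: 0 for n in names}
    for j in range(aln.n_cols):
        present = []
        for n in names:
            if aln.row(n)[j] != "-":
                present.append((n, counters[n]))
                counters[n] += 1
        for x in range(len(present)):
            for y in range(x + 1, len(present)):
                out.add(tuple(sorted((present[x], present[y]))))
    return out
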