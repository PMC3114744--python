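"""Rooted binary phylogenetic trees with branch lengths.

A deliberately small tree type: every internal node has exactly two
children (polytomies are rejected — resolve them upstream), branch
lengths are non-negative reals in substitutions per site, and leaves
carry the sequence names. Node ids are assigned in a deterministic
pre-order so decompositions and schedules are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

from .errors import InvalidInputError


@dataclass
class TreeNode:
    node_id: int = -1
    name: Optional[str] = None          # leaf name; internal nodes unnamed
    length: float = 0.0                 # branch length to the parent
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    parent: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None and self.right is None

    def children(self) -> list["TreeNode"]:
        return [c for c in (self.left, self.right) if c is not None]


class PhyloTree:
    """A rooted, strictly binary tree over named leaves."""

    def __init__(self, root: TreeNode) -> None:
        self.root = root
        self._assign(root)
        names = [leaf.name for leaf in self.leaves()]
        if any(n is None for n in names):
            raise InvalidInputError("every leaf must carry a name")
        if len(set(names)) != len(names):
            raise InvalidInputError("leaf names must be unique")
        self._by_id = {n.node_id: n for n in self.nodes()}
        self._leaf_by_name = {leaf.name: leaf for leaf in self.leaves()}

    def _assign(self, root: TreeNode) -> None:
        """Pre-order ids; validate arity and branch lengths."""
        counter = 0
        stack = [(root, None)]
        while stack:
            node, parent = stack.pop()
            node.parent = parent
            node.node_id = counter
            counter += 1
            kids = [c for c in (node.left, node.right) if c is not None]
            if len(kids) == 1:
                raise InvalidInputError("unary node: tree must be strictly binary")
            if node.length < 0:
                raise InvalidInputError("negative branch length")
            if node.right is not None:
                stack.append((node.right, node))
            if node.left is not None:
                stack.append((node.left, node))
        self.n_nodes = counter

    # -- traversal -----------------------------------------------------

    def nodes(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if node.right is not None:
                stack.append(node.right)
            if node.left is not None:
                stack.append(node.left)

    def postorder(self, start: Optional[TreeNode] = None) -> Iterator[TreeNode]:
        node = start if start is not None else self.root
        if node.left is not None:
            yield from self.postorder(node.left)
        if node.right is not None:
            yield from self.postorder(node.right)
        yield node

    def leaves(self, start: Optional[TreeNode] = None) -> list[TreeNode]:
        return [n for n in self.postorder(start) if n.is_leaf]

    def leaf_names(self, start: Optional[TreeNode] = None) -> list[str]:
        return [n.name for n in self.leaves(start)]  # type: ignore[misc]

    def node(self, node_id: int) -> TreeNode:
        try:
            return self._by_id[node_id]
        except KeyError:
            raise InvalidInputError(f"no node with id {node_id}") from None

    def leaf(self, name: str) -> TreeNode:
        try:
            return self._leaf_by_name[name]
        except KeyError:
            raise InvalidInputError(f"no leaf named {name!r}") from None

    # -- metrics -------------------------------------------------------

    def path_length(self, a: TreeNode, b: TreeNode) -> float:
        """Sum of branch lengths on the path between two nodes."""
        anc_a: dict[int, float] = {}
        node, dist = a, 0.0
        while node is not None:
            anc_a[node.node_id] = dist
            dist += node.length
            node = node.parent
        node, dist = b, 0.0
        while node is not None:
            if node.node_id in anc_a:
                return dist + anc_a[node.node_id]
            dist += node.length
            node = node.parent
        raise InvalidInputError("nodes are not in the same tree")

    def total_length(self) -> float:
        return sum(n.length for n in self.nodes() if n.parent is not None)

    # -- serialization -------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                label = node.name or ""
            else:
                label = f"({fmt(node.left)},{fmt(node.right)})"
            if node.parent is None:
                return label
            return f"{label}:{node.length:.10g}"

        return fmt(self.root) + ";"

    def __repr__(self) -> str:
        return f"<PhyloTree {len(self.leaves())} leaves>"

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            return TreeNode(
                name=node.name,
                length=node.length,
                left=clone(node.left) if node.left else None,
                right=clone(node.right) if node.right else None,
            )

        return PhyloTree(clone(self.root))


def cherry(name_a: str, name_b: str, len_a: float = 1.0, len_b: float = 1.0) -> PhyloTree:
    """Two-leaf tree — the smallest valid phylogeny."""
    return PhyloTree(
        TreeNode(
            left=TreeNode(name=name_a, length=len_a),
            right=TreeNode(name=name_b, length=len_b),
        )
    )
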