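"""Synthetic neutral sequence evolution on a tree, with truth alignments.

The generator draws a random binary topology (Yule process) with
exponential branch lengths rescaled to a target total tree length, then
evolves a root sequence down the tree: HKY substitutions at each branch
length, followed by Poisson-count insertions and deletions with
geometrically distributed lengths. Homology is tracked through explicit
residue-to-parent maps, so the leaf sequences come with the exact truth
alignment (inserted residues are homologous to nothing outside their
subtree). Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import expm

from .constraints import Constraint, ConstraintSet
from .errors import InvalidInputError
from .msa import GAP, MultipleAlignment, SequenceRecord
from .tree import PhyloTree, TreeNode

BASES = "ACGT"
_TRANSITION = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one simulated alignment problem.

    Rates are events per site per unit branch length (substitutions per
    site); indel lengths are geometric with success parameter
    ``indel_length_p`` (mean ``1/p``).
    """

    n_leaves: int = 9
    root_length: int = 1000
    kappa: float = 2.0
    base_frequencies: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    insertion_rate: float = 0.02
    deletion_rate: float = 0.02
    indel_length_p: float = 0.5
    total_tree_length: float = 1.13
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise InvalidInputError("need at least 2 leaves")
        if self.root_length < 1:
            raise InvalidInputError("root_length must be positive")
        freqs = np.asarray(self.base_frequencies, dtype=float)
        if freqs.shape != (4,) or (freqs <= 0).any():
            raise InvalidInputError("base_frequencies must be 4 positive numbers")
        if abs(float(freqs.sum()) - 1.0) > 1e-9:
            raise InvalidInputError("base_frequencies must sum to 1")
        for rate in (self.insertion_rate, self.deletion_rate):
            if rate < 0:
                raise InvalidInputError("indel rates must be >= 0")
        if not 0 < self.indel_length_p <= 1:
            raise InvalidInputError("indel_length_p must be in (0, 1]")
        if self.kappa <= 0:
            raise InvalidInputError("kappa must be positive")
        if self.total_tree_length < 0:
            raise InvalidInputError("total_tree_length must be >= 0")


@dataclass
class TruthSet:
    """A simulated problem: tree, leaf sequences, and the true alignment."""

    tree: PhyloTree
    records: list[SequenceRecord]
    truth: MultipleAlignment

    def record_map(self) -> dict[str, str]:
        return {r.name: r.residues for r in self.records}


def hky_rate_matrix(
    kappa: float, freqs: Sequence[float]
) -> np.ndarray:
    """HKY85 rate matrix, scaled to one expected substitution per site."""
    pi = np.asarray(freqs, dtype=float)
    q = np.zeros((4, 4))
    for i, a in enumerate(BASES):
        for j, b in enumerate(BASES):
            if i == j:
                continue
            q[i, j] = pi[j] * (kappa if (a, b) in _TRANSITION else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(q)))
    return q / mu


def hky_transition_matrix(
    kappa: float, freqs: Sequence[float], t: float
) -> np.ndarray:
    """P(t) = exp(Q t) for the scaled HKY matrix."""
    return expm(hky_rate_matrix(kappa, freqs) * t)


def random_tree(n: int, total_length: float, seed: Optional[int] = None) -> PhyloTree:
    """Random binary topology (Yule splits) with exponential branch lengths
    rescaled so the branch-length sum equals ``total_length``."""
    if n < 2:
        raise InvalidInputError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    root = TreeNode(left=TreeNode(name="L1"), right=TreeNode(name="L2"))
    active = [root.left, root.right]
    for i in range(3, n + 1):
        # Yule: a uniformly chosen current tip splits into two
        k = int(rng.integers(len(active)))
        old = active[k]
        old.left = TreeNode(name=old.name)
        old.right = TreeNode(name=f"L{i}")
        old.name = None
        active[k] = old.left
        active.append(old.right)
    tree = PhyloTree(root)
    branches = [node for node in tree.postorder() if node.parent is not None]
    raw = rng.exponential(1.0, size=len(branches))
    scale = total_length / float(raw.sum()) if raw.sum() > 0 else 0.0
    for node, ln in zip(branches, raw):
        node.length = float(ln * scale)
    return tree


def _sample_geometric(rng: np.random.Generator, p: float) -> int:
    return int(rng.geometric(p))


def evolve(tree: PhyloTree, config: SimulationConfig) -> TruthSet:
    """Evolve a root sequence down ``tree`` under the given conditions.

    Per branch: HKY substitutions at the branch length, then
    Poisson-count deletions and insertions placed uniformly (deletions
    truncated at the sequence end), with geometric lengths. Homology maps
    (child residue -> parent residue or None for insertions) are kept per
    branch and assembled into the leaf truth alignment.
    """
    rng = np.random.default_rng(config.seed)
    pi = np.asarray(config.base_frequencies, dtype=float)
    root_seq = rng.choice(4, size=config.root_length, p=pi).astype(np.int8)

    child_seqs: dict[int, np.ndarray] = {tree.root.node_id: root_seq}
    parent_maps: dict[int, list[Optional[int]]] = {}
    pmat_cache: dict[float, np.ndarray] = {}

    def transition(t: float) -> np.ndarray:
        if t not in pmat_cache:
            pmat_cache[t] = hky_transition_matrix(config.kappa, pi, t)
        return pmat_cache[t]

    for node in _preorder(tree.root):
        if node.parent is None:
            continue
        parent_seq = child_seqs[node.parent.node_id]
        t = node.length
        n = len(parent_seq)
        seq = parent_seq.copy()
        if t > 0 and n > 0:
            pmat = transition(t)
            u = rng.random(n)
            cum = np.cumsum(pmat, axis=1)
            seq = np.empty(n, dtype=np.int8)
            for b in range(4):
                mask = parent_seq == b
                if mask.any():
                    seq[mask] = np.searchsorted(cum[b], u[mask], side="right")
            seq = np.clip(seq, 0, 3).astype(np.int8)
        pmap: list[Optional[int]] = list(range(n))
        if t > 0 and n > 0:
            n_del = int(rng.poisson(config.deletion_rate * t * n))
            for _ in range(n_del):
                if len(seq) == 0:
                    break
                start = int(rng.integers(len(seq)))
                length = _sample_geometric(rng, config.indel_length_p)
                end = min(start + length, len(seq))
                seq = np.concatenate([seq[:start], seq[end:]])
                pmap = pmap[:start] + pmap[end:]
            n_ins = int(rng.poisson(config.insertion_rate * t * n))
            for _ in range(n_ins):
                pos = int(rng.integers(len(seq) + 1))
                length = _sample_geometric(rng, config.indel_length_p)
                ins = rng.choice(4, size=length, p=pi).astype(np.int8)
                seq = np.concatenate([seq[:pos], ins, seq[pos:]])
                pmap = pmap[:pos] + [None] * length + pmap[pos:]
        child_seqs[node.node_id] = seq
        parent_maps[node.node_id] = pmap

    names, rows = _truth_alignment(tree, child_seqs, parent_maps)
    leaf_names = set(tree.leaf_names())
    keep = [i for i, n in enumerate(names) if n in leaf_names]
    truth = MultipleAlignment(
        [names[i] for i in keep], [rows[i] for i in keep], validate=False
    ).drop_all_gap_columns()
    records = [
        SequenceRecord(n, _to_str(child_seqs[tree.leaf(n).node_id]))
        for n in tree.leaf_names()
    ]
    truth.check_projection({r.name: r.residues for r in records})
    return TruthSet(tree=tree, records=records, truth=truth)


def _to_str(seq: np.ndarray) -> str:
    return "".join(BASES[b] for b in seq)


def _preorder(root: TreeNode):
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        if node.right is not None:
            stack.append(node.right)
        if node.left is not None:
            stack.append(node.left)


def _truth_alignment(tree, seqs, maps):
    """Assemble the leaf alignment from the per-branch homology maps.

    Recursively builds, per node, an alignment whose rows are the node
    itself and all leaves below it; children splice in through the
    residue maps (unmapped = inserted residues become columns gapped
    outside their subtree).
    """

    def build(node: TreeNode) -> tuple[list[str], list[list[int]]]:
        """Returns (row names, columns); each column is a list of residue
        indices aligned in that column, -1 for a gap; row 0 is the node."""
        seq = seqs[node.node_id]
        if node.is_leaf:
            return [node.name], [[i] for i in range(len(seq))]
        names: list[str] = [f"@{node.node_id}"]
        child_results = []
        for child in node.children():
            c_names, c_cols = build(child)
            # residue index of the child row -> column position in c_cols
            child_row_cols = {}
            for col_idx, col in enumerate(c_cols):
                if col[0] >= 0:
                    child_row_cols[col[0]] = col_idx
            child_results.append((c_names, c_cols, child_row_cols, child))
            names.extend(c_names)
        width = sum(len(cr[0]) for cr in child_results)
        columns: list[list[int]] = []

        def gap_col() -> list[int]:
            return [-1] * (1 + width)

        # residues of each child mapping to each parent residue
        to_parent: list[dict[int, int]] = []
        for c_names, c_cols, _, child in child_results:
            m = maps[child.node_id]
            to_parent.append(
                {pr: ci for ci, pr in enumerate(m) if pr is not None}
            )
        cursors = [0] * len(child_results)

        def flush_child(ci: int, upto: int, out: list[list[int]]) -> None:
            c_names, c_cols, _, _ = child_results[ci]
            offset = 1 + sum(len(cr[0]) for cr in child_results[:ci])
            while cursors[ci] < upto:
                col = gap_col()
                src = c_cols[cursors[ci]]
                col[offset : offset + len(c_names)] = src
                out.append(col)
                cursors[ci] += 1

        for pr in range(len(seq)):
            staged: list[list[int]] = []
            targets = []
            for ci, (c_names, c_cols, row_cols, child) in enumerate(child_results):
                cres = to_parent[ci].get(pr)
                if cres is not None and cres in row_cols:
                    target = row_cols[cres]
                    flush_child(ci, target, staged)
                    targets.append((ci, target))
                else:
                    targets.append((ci, None))
            col = gap_col()
            col[0] = pr
            for ci, target in targets:
                if target is not None:
                    c_names, c_cols, _, _ = child_results[ci]
                    offset = 1 + sum(len(cr[0]) for cr in child_results[:ci])
                    col[offset : offset + len(c_names)] = c_cols[target]
                    cursors[ci] = target + 1
            staged.append(col)
            columns.extend(staged)
        for ci, (c_names, c_cols, _, _) in enumerate(child_results):
            flush_child(ci, len(c_cols), columns)
        return names, columns

    names, columns = build(tree.root)
    rows = []
    for r, name in enumerate(names):
        node = (
            tree.leaf(name)
            if not name.startswith("@")
            else tree.node(int(name[1:]))
        )
        seq = seqs[node.node_id]
        row = "".join(
            BASES[seq[col[r]]] if col[r] >= 0 else GAP for col in columns
        )
        rows.append(row)
    return names, rows


def constraints_from_truth(
    truth: TruthSet, fraction: float, seed: Optional[int] = None
) -> ConstraintSet:
    """Uniformly sample a fraction of the truth's residue–residue pairs as
    constraints; always consistent, being a subset of a real alignment."""
    if not 0 < fraction <= 1:
        raise InvalidInputError("fraction must be in (0, 1]")
    aln = truth.truth
    names = aln.names
    all_pairs: list[Constraint] = []
    counters = {n: 0 for n in names}
    rows = {n: aln.row(n) for n in names}
    for j in range(aln.n_cols):
        present = []
        for n in names:
            if rows[n][j] != GAP:
                present.append((n, counters[n]))
                counters[n] += 1
        for a in range(len(present)):
            for b in range(a + 1, len(present)):
                (na, pa), (nb, pb) = present[a], present[b]
                all_pairs.append(Constraint.make(na, pa, nb, pb))
    rng = np.random.default_rng(seed)
    k = max(1, int(round(fraction * len(all_pairs)))) if all_pairs else 0
    if k >= len(all_pairs):
        chosen = all_pairs
    else:
        idx = rng.choice(len(all_pairs), size=k, replace=False)
        chosen = [all_pairs[i] for i in sorted(idx)]
    return ConstraintSet(
        [SequenceRecord(r.name, r.residues) for r in truth.records], chosen
    )


def simulate(config: SimulationConfig) -> TruthSet:
    """Random tree + evolution in one call (tree seed derived from config)."""
    tree = random_tree(config.n_leaves, config.total_tree_length, config.seed)
    return evolve(tree, config)
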