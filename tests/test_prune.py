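"""Depth-wise decomposition, root inference, merging, and the pipeline."""

import numpy as np
import pytest

from metalign import (
    BuiltinAligner,
    MultipleAlignment,
    NearestLeafInference,
    SequenceRecord,
    SimulationConfig,
    agreement,
    cherry,
    infer_root_maximal,
    merge_alignments,
    min_stage_count,
    min_stage_decomposition,
    progressive_align,
    prune_align,
    select_outgroup,
    simulate,
)
from metalign.errors import InfeasibleError, InternalConsistencyError, InvalidInputError
from metalign.tree import PhyloTree, TreeNode

from oracles import all_tree_shapes, min_stages_exhaustive


def balanced_tree(depth: int) -> PhyloTree:
    counter = [0]

    def build(d):
        if d == 0:
            counter[0] += 1
            return TreeNode(name=f"L{counter[0]}", length=1.0)
        return TreeNode(left=build(d - 1), right=build(d - 1), length=1.0)

    root = build(depth)
    root.length = 0.0
    return PhyloTree(root)


class TestDecomposition:
    def test_two_leaf_tree_takes_two_stages(self):
        tree = cherry("A", "B")
        d = min_stage_decomposition(tree, 2)
        assert d.stage_count == 2 == min_stages_exhaustive(tree, 2)
        assert len(d.problems) == 1
        assert d.problems[0].frontier == [("leaf", "A"), ("leaf", "B")]

    def test_balanced_four_leaves_single_subtree(self):
        tree = balanced_tree(2)
        d = min_stage_decomposition(tree, 4)
        assert d.stage_count == 2 == min_stages_exhaustive(tree, 4)
        assert len(d.problems) == 1
        assert len(d.problems[0].frontier) == 4

    def test_balanced_eight_leaves_progressive_schedule(self):
        tree = balanced_tree(3)
        d = min_stage_decomposition(tree, 2)
        assert d.stage_count == min_stages_exhaustive(tree, 2)
        assert len(d.problems) == 7  # one per internal node

    def test_m_below_two_infeasible(self):
        with pytest.raises(InfeasibleError):
            min_stage_decomposition(cherry("A", "B"), 1)

    @pytest.mark.parametrize("n", range(2, 8))
    def test_optimal_on_all_shapes(self, n):
        """DP stage count equals the exhaustive-enumeration minimum for
        every rooted binary shape and every feasible cap."""
        for tree in all_tree_shapes(n):
            for m in range(2, n + 1):
                assert min_stage_count(tree, m) == min_stages_exhaustive(tree, m)

    def test_stage_count_non_increasing_in_m(self):
        from metalign import random_tree

        for seed in range(5):
            tree = random_tree(9, 2.0, seed=seed)
            counts = [min_stage_count(tree, m) for m in range(2, 10)]
            assert counts == sorted(counts, reverse=True)

    def test_decomposition_structure_invariants(self):
        from metalign import random_tree

        tree = random_tree(12, 3.0, seed=4)
        d = min_stage_decomposition(tree, 4)
        leaves = []
        roots = {p.root_id for p in d.problems}
        by_root = d.by_root()
        for p in d.problems:
            assert 1 <= len(p.frontier) <= 4
            for kind, ref in p.frontier:
                if kind == "leaf":
                    leaves.append(ref)
                else:
                    assert ref in roots
                    # a sub-tree's stage exceeds every child sub-tree's stage
                    assert by_root[ref].stage < p.stage
        assert sorted(leaves) == sorted(tree.leaf_names())
        assert tree.root.node_id in roots


class TestMaximalInference:
    def test_strict_majority(self):
        aln = MultipleAlignment.from_pairs([("a", "A"), ("b", "A"), ("c", "G")])
        assert infer_root_maximal(aln) == "A"

    def test_tie_breaks_alphabetically(self):
        aln = MultipleAlignment.from_pairs([("a", "A"), ("b", "C"), ("c", "G")])
        assert infer_root_maximal(aln) == "A"
        aln2 = MultipleAlignment.from_pairs([("a", "T"), ("b", "G"), ("c", "C")])
        assert infer_root_maximal(aln2) == "C"

    def test_length_equals_column_count(self, backend, small_truth):
        aln = backend.align(small_truth.records[:3])
        assert len(infer_root_maximal(aln)) == aln.n_cols

    def test_gaps_do_not_vote(self):
        aln = MultipleAlignment.from_pairs([("a", "A-"), ("b", "-T"), ("c", "AT")])
        assert infer_root_maximal(aln) == "AT"


class TestOutgroup:
    def test_whole_tree_has_no_outgroup(self):
        tree = cherry("A", "B")
        assert select_outgroup(tree, tree.root.node_id) is None

    def test_nearest_by_branch_length(self):
        # ((A:1,B:1):1,(C:1,D:5):1); sub-tree = parent of A,B -> C at 3 < D at 7
        root = TreeNode(
            left=TreeNode(
                left=TreeNode(name="A", length=1), right=TreeNode(name="B", length=1),
                length=1,
            ),
            right=TreeNode(
                left=TreeNode(name="C", length=1), right=TreeNode(name="D", length=5),
                length=1,
            ),
        )
        tree = PhyloTree(root)
        sub = tree.root.left.node_id
        assert select_outgroup(tree, sub) == "C"

    def test_tie_breaks_on_leaf_name(self):
        root = TreeNode(
            left=TreeNode(
                left=TreeNode(name="A", length=1), right=TreeNode(name="B", length=1),
                length=1,
            ),
            right=TreeNode(
                left=TreeNode(name="D", length=1), right=TreeNode(name="C", length=1),
                length=1,
            ),
        )
        tree = PhyloTree(root)
        assert select_outgroup(tree, tree.root.left.node_id) == "C"


class TestMerge:
    def test_bijective_guides_splice_without_new_columns(self):
        parent = MultipleAlignment.from_pairs([("g1", "ACG"), ("g2", "ACG")])
        child1 = MultipleAlignment.from_pairs([("x", "AAG"), ("y", "ACG")])
        child2 = MultipleAlignment.from_pairs([("u", "ACG"), ("v", "TCG")])
        merged, cmap = merge_alignments(
            parent,
            {"g1": (child1, [0, 1, 2]), "g2": (child2, [0, 1, 2])},
        )
        assert merged.n_cols == parent.n_cols
        assert merged.names == ["x", "y", "u", "v"]
        assert merged.row("x") == "AAG" and merged.row("v") == "TCG"
        assert cmap == [0, 1, 2]

    def test_single_leaf_child_relabels(self):
        parent = MultipleAlignment.from_pairs([("g", "AC-G"), ("z", "ACTG")])
        child = MultipleAlignment.from_pairs([("leaf", "ACG")])
        merged, _ = merge_alignments(parent, {"g": (child, [0, 1, 2])})
        assert merged.names == ["leaf", "z"]
        assert merged.row("leaf") == "AC-G"
        assert merged.row("z") == "ACTG"

    def test_unmapped_child_columns_inserted(self):
        # guide covers child columns 0 and 2; column 1 must be re-inserted
        parent = MultipleAlignment.from_pairs([("g", "AG"), ("z", "AG")])
        child = MultipleAlignment.from_pairs([("x", "A-G"), ("y", "ATG")])
        merged, _ = merge_alignments(parent, {"g": (child, [0, 2])})
        assert merged.row("x") == "A-G"
        assert merged.row("y") == "ATG"
        assert merged.row("z") == "A-G"

    def test_gapped_guides_match_naive_expansion(self):
        """Merging equals rebuilding the alignment column by column."""
        parent = MultipleAlignment.from_pairs(
            [("g1", "AC--GT"), ("g2", "-CTA-T"), ("z", "ACT-GT")]
        )
        child1 = MultipleAlignment.from_pairs([("x", "ACG-T"), ("y", "AC-TT")])
        child2 = MultipleAlignment.from_pairs([("u", "CTAT"), ("v", "C-AT")])
        g1_map = [j for j, ch in enumerate(child1.row("x")) if ch != "-"]
        # guide g1 has residues ACGT; its row in child1 is x = ACG-T
        merged, _ = merge_alignments(
            parent, {"g1": (child1, g1_map), "g2": (child2, [0, 1, 2, 3])}
        )
        # naive expansion oracle: walk parent columns, splice child columns
        def expand():
            rows = {n: [] for n in ["x", "y", "u", "v", "z"]}
            r1 = r2 = 0
            for c in range(parent.n_cols):
                cells = {"z": parent.row("z")[c]}
                if parent.row("g1")[c] != "-":
                    j = g1_map[r1]; r1 += 1
                    cells["x"] = child1.row("x")[j]; cells["y"] = child1.row("y")[j]
                else:
                    cells["x"] = cells["y"] = "-"
                if parent.row("g2")[c] != "-":
                    j = r2; r2 += 1
                    cells["u"] = child2.row("u")[j]; cells["v"] = child2.row("v")[j]
                else:
                    cells["u"] = cells["v"] = "-"
                for n, ch in cells.items():
                    rows[n].append(ch)
            # child1 column 3 is unmapped (x gapped): insert before column of x's T
            return rows
        rows = expand()
        for name in ["u", "v", "z"]:
            assert merged.projection(name) == "".join(rows[name]).replace("-", "")
        assert merged.projection("x") == child1.projection("x")
        assert merged.projection("y") == child1.projection("y")
        # the unmapped child1 column was re-inserted: y keeps its T residue
        assert merged.n_cols == parent.n_cols + 1

    def test_non_monotone_guide_map_rejected(self):
        parent = MultipleAlignment.from_pairs([("g", "AC"), ("z", "AC")])
        child = MultipleAlignment.from_pairs([("x", "CA")])
        with pytest.raises(InternalConsistencyError):
            merge_alignments(parent, {"g": (child, [1, 0])})


class TestPruneAlign:
    def test_identity_reduction_when_m_covers_all(self, backend, small_truth):
        direct = backend.align(small_truth.records, small_truth.tree)
        via_prune = prune_align(
            small_truth.records, small_truth.tree, M=len(small_truth.records),
            backend=backend,
        )
        assert via_prune == direct

    @pytest.mark.parametrize("seed", range(4))
    def test_progressive_equivalence(self, backend, seed):
        """M=2 + nearest-leaf inference + no out-groups + serial is exactly
        progressive alignment on the same guide tree."""
        ts = simulate(
            SimulationConfig(n_leaves=6 + seed, root_length=150, seed=400 + seed)
        )
        via_prune = prune_align(
            ts.records, ts.tree, M=2, backend=backend,
            inference=NearestLeafInference(), use_outgroups=False,
        )
        direct = progressive_align(ts.records, ts.tree)
        assert via_prune == direct

    def test_projection_conservation(self, backend, small_truth):
        for m in (2, 3, 4):
            aln = prune_align(
                small_truth.records, small_truth.tree, M=m, backend=backend,
                use_outgroups=True,
            )
            for rec in small_truth.records:
                assert aln.projection(rec.name) == rec.residues

    def test_outgroups_do_not_break_pipeline(self, backend, small_truth):
        with_og = prune_align(
            small_truth.records, small_truth.tree, M=2, backend=backend,
            use_outgroups=True,
        )
        assert sorted(with_og.names) == sorted(r.name for r in small_truth.records)

    def test_missing_sequence_rejected(self, backend, small_truth):
        with pytest.raises(InvalidInputError):
            prune_align(
                small_truth.records[:-1], small_truth.tree, M=3, backend=backend
            )

    def test_moderate_cap_close_to_full_alignment(self, backend):
        """Capping the sub-tree size should barely change accuracy on a
        low-divergence problem."""
        ts = simulate(
            SimulationConfig(
                n_leaves=12, root_length=300, total_tree_length=0.8, seed=55
            )
        )
        full = prune_align(ts.records, ts.tree, M=12, backend=backend)
        capped = prune_align(ts.records, ts.tree, M=5, backend=backend)
        a_full = agreement(full, ts.truth)
        a_capped = agreement(capped, ts.truth)
        assert a_capped >= a_full - 0.05
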