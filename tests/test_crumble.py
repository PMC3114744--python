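"""Separations, block tiling, trimming, and the length-wise pipeline."""

import pytest

from metalign import (
    Constraint,
    ConstraintSet,
    ExecutorConfig,
    MultipleAlignment,
    SequenceRecord,
    SimulationConfig,
    constraints_from_truth,
    crumble_align,
    find_separation,
    simulate,
    tile_blocks,
    trim_block_alignment,
)
from metalign.errors import InvalidInputError

from oracles import PositionOrderOracle, aligned_pairs


def cset(seqs, pairs):
    records = [SequenceRecord(n, r) for n, r in seqs]
    return ConstraintSet(records, [Constraint.make(*p) for p in pairs])


def full_column(names, length, col):
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairs.append((names[i], col, names[j], col))
    return pairs


class TestFindSeparation:
    def test_fully_aligned_column_has_width_one(self):
        names = ["A", "B", "C"]
        cs = cset(
            [(n, "ACGTACGT") for n in names], full_column(names, 8, 3)
        )
        sep = find_separation(cs, ("A", 3))
        for n in names:
            assert sep.intervals[n] == (3, 4)

    def test_empty_constraints_extend_to_sequence_ends(self):
        cs = cset([("A", "ACGTAC"), ("B", "ACGT")], [])
        sep = find_separation(cs, ("A", 2))
        assert sep.intervals["A"] == (2, 3)
        assert sep.intervals["B"] == (0, 4)  # nothing bounds the search

    def test_staircase_matches_poset_oracle(self):
        # staggered constraints over three sequences
        cs = cset(
            [("A", "ACGTACGTAC"), ("B", "ACGTACGTAC"), ("C", "ACGTACGTAC")],
            [("A", 2, "B", 4), ("B", 6, "C", 3), ("A", 7, "C", 8)],
        )
        oracle = PositionOrderOracle(cs)
        for anchor in [("A", 2), ("B", 5), ("C", 0), ("A", 9)]:
            sep = find_separation(cs, anchor)
            ub = oracle.least_upper_bounds(anchor)
            lb = oracle.greatest_lower_bounds(anchor)
            for name in ["A", "B", "C"]:
                lo, hi = sep.intervals[name]
                assert hi == (ub[name] + 1 if ub[name] is not None else 10)
                want_lo = lb[name] if lb[name] is not None else 0
                assert lo == min(want_lo, hi)

    def test_inconsistent_constraints_rejected(self):
        cs = cset([("A", "ACGT"), ("B", "ACGT")], [("A", 0, "B", 1), ("A", 1, "B", 0)])
        with pytest.raises(InvalidInputError):
            find_separation(cs, ("A", 0))


class TestTileBlocks:
    def test_huge_core_gives_single_block(self):
        cs = cset([("A", "ACGTACGT"), ("B", "ACGTACGT")], [("A", 4, "B", 4)])
        tiling = tile_blocks(cs, core_size=100)
        assert len(tiling) == 1
        block = tiling.blocks[0]
        assert block.interval == {"A": (0, 8), "B": (0, 8)}
        assert block.left is None and block.right is None

    def test_fully_constrained_identical_sequences(self):
        length = 40
        names = ["A", "B", "C"]
        seq = "ACGTTGCAATCGGCTAGCTTAGCGCATTGCAGCTAGGCTA"
        pairs = []
        for col in range(length):
            pairs.extend(full_column(names, length, col))
        cs = cset([(n, seq) for n in names], pairs)
        tiling = tile_blocks(cs, core_size=10)
        assert len(tiling) == 4
        for block in tiling.blocks:
            for sep in (block.left, block.right):
                if sep is not None:
                    assert all(hi - lo == 1 for lo, hi in sep.intervals.values())
        # cores are pairwise disjoint and cover the sequence with separations
        for n in names:
            covered = []
            for block in tiling.blocks:
                lo, hi = block.core(n)
                covered.extend(range(lo, hi))
            assert len(covered) == len(set(covered))

    def test_truncation_forces_fixed_blocks(self):
        cs = cset([("A", "A" * 30), ("B", "C" * 30)], [])
        tiling = tile_blocks(cs, core_size=10, max_block_size=10)
        for block in tiling.blocks:
            for n in ("A", "B"):
                lo, hi = block.interval[n]
                assert hi - lo == 10
        assert len(tiling) == 3

    def test_coverage_and_overlap_invariants(self, small_truth):
        cs = constraints_from_truth(small_truth, 0.5, seed=8)
        tiling = tile_blocks(cs, core_size=60, max_block_size=200)
        for rec in small_truth.records:
            n = rec.name
            pos = 0
            for k, block in enumerate(tiling.blocks):
                lo, hi = block.interval[n]
                # adjacent blocks overlap exactly in the shared separation
                if block.left is not None:
                    assert lo == block.left.start(n)
                    prev_hi = tiling.blocks[k - 1].interval[n][1]
                    assert prev_hi == block.left.end(n)
                assert lo <= hi
                assert lo == min(pos, lo)
                pos = hi
            assert pos == len(rec)

    def test_monotone_block_count_in_core_size(self, small_truth):
        cs = constraints_from_truth(small_truth, 0.5, seed=8)
        counts = [
            len(tile_blocks(cs, core_size=c)) for c in (20, 40, 80, 160, 1000)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_bad_core_size_rejected(self, small_truth):
        cs = constraints_from_truth(small_truth, 0.2, seed=1)
        with pytest.raises(InvalidInputError):
            tile_blocks(cs, core_size=0)


class TestTrim:
    def make_sep(self, intervals):
        from metalign.crumble import Separation

        return Separation(intervals)

    def test_empty_separation_is_noop(self):
        aln = MultipleAlignment.from_pairs([("A", "ACGT"), ("B", "ACGT")])
        sep = self.make_sep({"A": (4, 4), "B": (4, 4)})
        kept, removed = trim_block_alignment(aln, "right", sep, {"A": 0, "B": 0})
        assert kept == aln
        assert removed == {"A": "", "B": ""}

    def test_gapless_suffix_trim(self):
        rows = [("S1", "ACGTACGTACGT"), ("S2", "ACGTACGTACGT"), ("S3", "ACGTACGTACGT")]
        aln = MultipleAlignment.from_pairs(rows)
        sep = self.make_sep({n: (9, 12) for n, _ in rows})
        kept, removed = trim_block_alignment(
            aln, "right", sep, {n: 0 for n, _ in rows}
        )
        assert kept.n_cols == 9
        for n, row in rows:
            assert kept.row(n) == row[:9]
            assert removed[n] == row[9:]

    def test_staggered_gaps_match_masking_oracle(self):
        aln = MultipleAlignment.from_pairs(
            [("A", "AC-GTA"), ("B", "ACT--A"), ("C", "-CTGTA")]
        )
        # remove the last 2 residues of A, last 1 of B, none of C
        sep = self.make_sep({"A": (3, 5), "B": (3, 4), "C": (5, 5)})
        kept, removed = trim_block_alignment(
            aln, "right", sep, {"A": 0, "B": 0, "C": 0}
        )
        # masking oracle: blank the suffix residues, drop empty columns
        def mask(row, keep_n):
            out, seen = [], 0
            for ch in row:
                if ch != "-" and seen >= keep_n:
                    out.append("-")
                else:
                    out.append(ch)
                    if ch != "-":
                        seen += 1
            return "".join(out)
        masked = {
            "A": mask(aln.row("A"), 3), "B": mask(aln.row("B"), 3),
            "C": mask(aln.row("C"), 5),
        }
        keep_cols = [
            j for j in range(6) if any(masked[n][j] != "-" for n in masked)
        ]
        for n in ("A", "B", "C"):
            assert kept.row(n) == "".join(masked[n][j] for j in keep_cols)
        assert removed["A"] == "TA" and removed["B"] == "A" and removed["C"] == ""
        # conservation: kept projection + removed == original residues
        for n in ("A", "B", "C"):
            assert kept.projection(n) + removed[n] == aln.projection(n)


class TestCrumbleAlign:
    def test_single_block_is_identity_reduction(self, backend, small_truth):
        cs = constraints_from_truth(small_truth, 0.3, seed=5)
        out = crumble_align(
            small_truth.records, cs, backend, core_size=10**6
        )
        assert out == backend.align(small_truth.records)

    def test_identical_sequences_stay_gapless(self, backend):
        seq = ("ACGTTGCAATCGGCTAGCTTAGCGCATTGCAGCTAGGCTA" * 8)[:300]
        records = [SequenceRecord(f"S{i}", seq) for i in range(9)]
        truth = MultipleAlignment.from_records(records)
        # constraints from the trivial truth alignment: the full diagonal
        pairs = []
        for col in range(300):
            for i in range(9):
                for j in range(i + 1, 9):
                    pairs.append(Constraint.make(f"S{i}", col, f"S{j}", col))
        cs = ConstraintSet(records, pairs)
        out = crumble_align(records, cs, backend, core_size=50)
        assert out.n_cols == 300
        from metalign import agreement

        assert agreement(out, truth) == 1.0

    def test_projection_conservation(self, backend, small_truth):
        cs = constraints_from_truth(small_truth, 0.4, seed=6)
        out = crumble_align(small_truth.records, cs, backend, core_size=50)
        for rec in small_truth.records:
            assert out.projection(rec.name) == rec.residues

    def test_truth_pairs_never_span_two_cores(self, backend):
        """With constraints sampled from the truth, no truth-aligned pair
        crosses a core boundary."""
        ts = simulate(
            SimulationConfig(n_leaves=5, root_length=600, seed=42)
        )
        cs = constraints_from_truth(ts, 0.3, seed=7)
        tiling = tile_blocks(cs, core_size=120)
        core_index = {}
        for k, block in enumerate(tiling.blocks):
            for name in cs.lengths:
                lo, hi = block.core(name)
                for i in range(lo, hi):
                    core_index[(name, i)] = k
        for (pa, pb) in aligned_pairs(ts.truth):
            ka, kb = core_index.get(pa), core_index.get(pb)
            if ka is not None and kb is not None:
                assert ka == kb, (pa, pb)

    def test_executor_mode_invariance(self, backend, small_truth):
        cs = constraints_from_truth(small_truth, 0.4, seed=6)
        serial = crumble_align(
            small_truth.records, cs, backend, core_size=60,
            executor=ExecutorConfig(jobs=1),
        )
        parallel = crumble_align(
            small_truth.records, cs, backend, core_size=60,
            executor=ExecutorConfig(jobs=4),
        )
        assert serial == parallel

    def test_inconsistent_constraints_rejected(self, backend):
        records = [SequenceRecord("A", "ACGT"), SequenceRecord("B", "ACGT")]
        cs = ConstraintSet(
            records,
            [Constraint.make("A", 0, "B", 1), Constraint.make("A", 1, "B", 0)],
        )
        with pytest.raises(InvalidInputError):
            crumble_align(records, cs, backend, core_size=2)
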