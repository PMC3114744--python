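# metalign

Partitioning very large multiple-sequence-alignment problems into
tractable sub-problems — *meta-alignment*. The package does not align
sequences itself so much as it orchestrates an existing global aligner:
it breaks a problem apart, delegates the pieces (in parallel), and
reassembles the results into one alignment whose every row still
projects exactly onto its input sequence.

Two orthogonal partitioners are provided:

- **Length-wise (`metalign.crumble`).** Sparse pairwise constraints
  (aligned base positions) impose a partial order ≺ on all residues:
  aligned positions are equal, and positions along one sequence
  increase. Around an anchor position *x* the method finds, per species
  *i*, the least position *aᵢ* with *x* ≼ *aᵢ* and the greatest
  position *bᵢ* ≼ *x*; the intervals [*bᵢ*, *aᵢ*] form a *separation*.
  Nothing left of a separation can be aligned past it, so the *cores*
  between consecutive separations are mutually unalignable and each
  *block* (core + flanking separations) can be aligned independently.
  Blocks are aligned in parallel, the shared separations are trimmed off
  and realigned on their own, and everything is concatenated.

- **Depth-wise (`metalign.prune`).** A rooted binary phylogeny is cut
  into sub-trees overlapping at internal nodes. Each sub-tree problem
  aligns its *frontier* — at most *M* sequences, counting leaves and the
  inferred root sequences of child sub-trees — optionally plus a nearby
  out-group leaf for context. Cut nodes are chosen by a dynamic program
  minimising the number of sequential *stages* S subject to the cap *M*
  (same-stage sub-trees run concurrently; a leaf counts as stage 1, a
  sub-tree completes one stage after the latest of its frontier
  members). Sub-alignments merge bottom-up through the inferred roots
  acting as guide rows. With *M* = 2, leaf-copy (nearest-leaf) root
  inference, no out-groups and serial execution, the procedure reduces
  bit-exactly to progressive alignment.

Around the two methods: a pluggable aligner-backend contract with a
deterministic built-in progressive aligner and a wrapper for external
command-line aligners; the *average agreement score* (fraction of a
predicted alignment's pairwise residue/gap events present in a truth
alignment, averaged over species pairs); a hierarchical job executor
with child/follow-on semantics; and a synthetic-evolution generator
(HKY substitutions plus indels on a random tree) that emits leaf
sequences together with the exact truth alignment.

## Worked example

```python
from metalign import (
    BuiltinAligner, SimulationConfig, agreement,
    constraints_from_truth, crumble_align, prune_align, simulate,
)

ts = simulate(SimulationConfig(n_leaves=9, root_length=2000,
                               total_tree_length=0.4, seed=11))
backend = BuiltinAligner()

direct = backend.align(ts.records, ts.tree)
print(round(agreement(direct, ts.truth), 4))     # 0.9916

cs = constraints_from_truth(ts, 0.3, seed=2)     # sparse constraints
blocks = crumble_align(ts.records, cs, backend, core_size=500)
print(round(agreement(blocks, ts.truth), 4))     # 0.9788

subtrees = prune_align(ts.records, ts.tree, M=4, backend=backend)
print(round(agreement(subtrees, ts.truth), 4))   # 0.9894
```

A 9-species, ~2 kb simulated problem at low divergence: aligning the
whole problem directly scores 0.9916 against the known truth; breaking
it into ~500 bp blocks from a 30% sample of the true constraints loses
about 0.013 of agreement, and capping sub-trees at 4 sequences loses
about 0.002 — the partitioned runs stay close to the unpartitioned one,
which is the point of the method.

The same flows are available from the shell:

```bash
metalign simulate --leaves 9 --length 2000 --seed 11 --out-prefix sim
metalign constraints --fasta sim.fa --kmer 12 --out sim.tsv
metalign crumble --fasta sim.fa --constraints sim.tsv --core-size 500 \
    --jobs 4 --out out.fa
metalign prune --fasta sim.fa --tree sim.nwk --max-subtree 4 --out out.fa
metalign align --fasta sim.fa --tree sim.nwk --max-subtree 4 \
    --core-size 500 --out out.fa        # both partitioners composed
metalign score --pred out.fa --truth sim.true.fa
```

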