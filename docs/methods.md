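# Methods

This note records the models and procedures the package implements, the
design choices made where the design was genuinely open, the numerical
conventions, and what the synthetic-data generator does and does not
emulate. Coordinates are 0-based and intervals half-open `[start, end)`
everywhere inside the library; file-format conventions (e.g. MAF) are
applied only at the writer boundary.

## Sparse constraints and the position partial order

A constraint aligns one base position of one sequence with one base
position of another; constraints are stored symmetric and deduplicated,
since alignment of positions is an equivalence. The induced relation —
aligned positions equal, within-sequence positions increasing — is a
partial order exactly when the graph over equivalence classes of aligned
positions (with directed edges between consecutive constrained positions
along each sequence) is acyclic; `check_consistency` tests this via
strongly connected components and reports the constraints implicated in
cycles.

Order queries (`precedes`, and the bound computations behind
separations) run a worklist fixpoint: per sequence, track the extreme
position known comparable with the query point, and propagate through
aligned-position classes. Each constrained position expands at most once
per query, so a query is linear in the number of constraints.
Correctness is anchored in the tests to breadth-first reachability over
the complete position graph.

### Anchor generation

The constraint generator is a deliberately simple stand-in for a real
pairwise constraint system: per sequence pair it takes exact-match
k-mers unique in both sequences (N matches only N, for determinism),
merges same-diagonal overlapping hits into runs, chains runs to a
maximum-coverage non-crossing subset (weighted longest increasing
subsequence), and expands the chain base by base. Cross-pair conflicts
can survive chaining; they are repaired greedily — recheck consistency
and drop the lexicographically first constraint implicated in a cycle
until the set is a partial order. The rule is arbitrary but fixed, and
the generator's output is always consistent by construction plus repair.

## Length-wise partitioning

Around an anchor position `x`, the separation is computed per species
`i` as the interval `[b_i, a_i]` (stored half-open as `[b_i, a_i + 1)`),
where `a_i` is the least position with `x ≼ a_i` and `b_i` the greatest
position with `b_i ≼ x`. When no such position exists the interval
extends to the sequence end (`a_i`) or start (`b_i`) — a species with no
bounding constraint simply has no residues that are provably on one
side, so the whole flank is treated as ambiguous. This choice is what
makes the core-independence guarantee hold without constraints spanning
all species:

> If the constraints are a subset of the true alignment, any residue
> `p < b_i` satisfies `p ≺ x ≼ a_j` for every species `j`, so in the
> truth `p` sits in a strictly earlier column than any residue
> `q > a_j`. Hence no truth-aligned pair can have one member before one
> separation and the other after it: truth pairs never span two cores.

Tiling scans left to right, paced by the first input sequence (the
*reference*; the choice is arbitrary but fixed): each step anchors a
separation roughly `core_size` residues past the previous separation's
end in the reference. Per species the new separation is clamped to start
no earlier than the previous one ended (residues displaced by the clamp
move from separation to core; the displaced residues still satisfy
`p ≼ x`, so independence of *cores* is unaffected). A block is the
interval from the start of its left separation to the end of its right
one.

**Truncation.** If a block would exceed `max_block_size` residues in a
species, it is cut at the cap there and the shared boundary becomes
empty — blocks abut exactly at the cut and the truncated sequence
becomes part of the next block. The independence guarantee is void
across truncated boundaries; truncation is a memory/runtime safety
valve, not a correctness device. After the reference sequence is
exhausted, the final block absorbs all remainders, still chunked at the
cap when one is set.

**Trim and reassembly.** Each internal separation belongs to both
neighbouring blocks. After block alignment, the separation's residues
are masked to gaps on both flanks (they form a contiguous prefix/suffix
of each row by construction), all-gap columns are dropped, and the
pooled separation residues are realigned as their own sub-problem
(sub-problems with at most one non-empty species skip the backend).
Kept blocks and separation alignments concatenate in order; rows missing
from a piece are padded with gaps. Every input residue therefore appears
exactly once, in order — the projection invariant is asserted at the end
of every pipeline run.

## Depth-wise partitioning

### The stage recurrence

Let `T[v][j]` be the minimum number of stages needed when the sub-tree
below node `v` contributes exactly `j` sequences (leaves or inferred
roots) to the sub-tree problem that encloses `v`:

- leaf `v`: `T[v][1] = 1` (the trivial single-sequence stage is counted
  — time is spent extracting the sequence), `T[v][j>1] = ∞`;
- internal `v`, `j ≥ 2` (`v` dissolves into the enclosing problem):
  `T[v][j] = min over j_l + j_r = j of max(T[left][j_l], T[right][j_r])`;
- internal `v`, `j = 1` (`v` is a cut node rooting its own problem):
  `T[v][1] = 1 + min over j_l + j_r ≤ M of max(T[left][j_l],
  T[right][j_r])`.

The answer for the whole tree is `T[root][1]`. For fixed `M` the DP is
linear in the number of leaves (`O(N·M²)`). Ties break toward the
smallest left share, so decompositions are reproducible. Correctness is
anchored to exhaustive enumeration over all cut sets in the tests, for
every rooted binary shape up to 7 leaves and random larger trees — the
recurrence was reconstructed from prose, so the enumeration oracle, not
the algebra, is the authority. Note the convention above counts the leaf
stage: a single sub-tree spanning the whole tree completes at stage 2.
Non-binary trees are rejected (the recurrence is defined for two
children; resolve polytomies upstream). `M ≥ 2` is required; `M = 2` is
always feasible.

### Root inference and merging

Each sub-tree problem aligns its frontier in post-order (the built-in
backend receives the induced sub-tree — the original subtree truncated
at cut nodes — as its guide tree), then infers a root sequence:

- **Maximal**: per column, the most frequent non-gap base, ties broken
  `A < C < G < T < N`; one base per column, so the guide map onto the
  sub-alignment's columns is a bijection and the inferred sequence is
  the longest root consistent with the alignment. All-gap columns are
  prohibited (and never produced).
- **Nearest-leaf**: copy the row whose underlying leaf is closest to the
  sub-tree root by branch length (ties on the leaf name); the guide map
  is injective but not surjective.

An out-group — the leaf outside the sub-tree closest to its root by
branch length, ties on name — can be added to each sub-problem for
context; its row is dropped immediately after alignment, before
inference, and it does not count toward `M`. If the selected out-group
would duplicate a frontier name it is skipped.

Merging expands bottom-up: the parent problem's alignment is the frame;
each inferred-root row is a guide whose residues map onto columns of the
(already expanded) child alignment. Parent columns where the guide has a
residue splice in the mapped child column; where the guide is gapped,
child rows get gaps; child columns never reached by the guide map
(possible only with nearest-leaf guides) are inserted as new columns,
gapped elsewhere, immediately before the next mapped column. Guide rows
are removed from the output (a keep-internal-nodes flag exists on the
merge primitive). Column maps are threaded through the expansion so that
Maximal guides, whose maps are stated in the coordinates of the
unexpanded child, stay valid.

### The built-in progressive aligner

The backend contract: a deterministic map from sequence records (plus an
optional guide tree) to an alignment whose rows project to the inputs; a
single sequence is returned unchanged; every backend result — built-in
or external — is projection-checked before use.

The built-in aligner is progressive over a guide tree (neighbour joining
on a shared-k-mer distance, k = 6, name-based tie-breaks, when no tree
is given). At each internal node it pairwise-aligns one *representative
leaf* from each side — the leaf nearest the node by branch length, ties
on name — with affine-gap global dynamic programming, then expands the
two child sub-alignments through the representatives as guide rows,
using the same merge primitive as the depth-wise pipeline. Merging
through leaf representatives rather than profile columns is a deliberate
design choice: it makes progressive alignment literally the `M = 2` /
nearest-leaf / no-out-group / serial special case of the depth-wise
pipeline, and that equivalence is asserted bit-exactly in the tests. A
sum-of-pairs profile merger would be a stronger aligner but could not
satisfy the reduction exactly; since the package's subject is the
partitioning, not the aligner, the reduction won.

Pairwise DP: three-state Gotoh under maximisation, default scores match
+1 / mismatch −1 / gap open −2 / gap extend −1 (conventional values, not
calibrated). The horizontal-gap state is computed row-wise with a
running-maximum trick (a gap run opened after column `k` scores
`best(M, X)[i, k] + open + extend·(j − k − 1)`), so each row is a few
vectorised passes. Traceback ties prefer diagonal, then a gap in the
second sequence, then a gap in the first; within a gap state, closing
the gap is preferred. All scores are integer-valued in float64, so tie
comparisons are exact. Optimality is verified against exhaustive path
enumeration for short sequences.

## Agreement score

For each species pair, an alignment induces ordered events: residue i
aligned to residue j, residue aligned to gap, gap aligned to residue;
columns gapped in both species are dropped. The score of a prediction
against a truth is the fraction of the *predicted* events present in the
truth, averaged over all species pairs — the denominator is the
prediction's event count, so the measure is intentionally asymmetric
(identical alignments score 1, alignments sharing no event score 0).
Gap–gap columns are excluded by the projection convention. For deep
problems the average can be estimated over a seeded, without-replacement
sample of pairs; the estimator is unbiased and the tests check it
against the full average within sampling error.

## Job executor

A job has an action, children (which the action may create dynamically),
and an optional follow-on that runs only after the job and *all* its
descendants have completed. Scheduling is intra-process — a deterministic
serial FIFO and a thread-pool mode — replacing the original design's
on-disk handoff to a cluster batch system; the ordering and failure
contract is preserved, the transport is not. On failure the run stops,
pending jobs are cancelled, and the error names the failed job and its
ancestry. Actions write results into their own slots, so serial and
parallel runs give bit-identical pipeline outputs (asserted in the
tests). Attaching a job twice is a scheduling error, which is how cycles
are excluded. In the combined pipeline each sub-tree job runs the
length-wise partitioner with its own executor, i.e. jobs spawn their own
parallel sub-jobs.

## Synthetic data

The generator emulates neutral DNA evolution: a random binary topology
(Yule splits), exponential branch lengths rescaled to a target total
tree length; a root sequence drawn from the equilibrium frequencies; per
branch, HKY substitutions using the exact transition matrix
`P(t) = exp(Qt)` with `Q` scaled to one expected substitution per site,
then Poisson-count deletions followed by insertions (counts proportional
to rate × branch length × current length), placed uniformly, with
geometric lengths; deletions truncate at sequence ends. Homology is
tracked as explicit child-residue → parent-residue maps, so the truth
alignment is exact and inserted residues are homologous to nothing
outside their subtree. Defaults: κ = 2, uniform base frequencies,
insertion = deletion = 0.02 events/site/unit-length, geometric length
parameter 0.5 (mean 2), total tree length 1.13 substitutions/site —
conventional neutral-simulation values; the indel parameters are
documented choices, not calibrated to any dataset.

What it does not emulate: retrotransposon or other structured
insertions, rate heterogeneity across sites, selection, rearrangements,
and base composition drift. Passing tests therefore demonstrate the
partitioners' bookkeeping and guarantees under clean neutral evolution,
not alignment accuracy on real genomes.

## Problem sizes and tolerances in the tests

The test suite runs everything at desk scale: decomposition optimality
is exhaustive over tree shapes to 7 leaves plus 100 random 8–10-leaf
trees; order-oracle equivalence uses 200 random constraint sets of at
most 200 residues; projection conservation runs 50 seeded instances;
separation soundness uses ten 5-species ~2 kb simulations; the
simulator's transition:transversion check uses one 50 kb branch and a
3-standard-error band. Bit-exact assertions (identity reductions,
progressive equivalence, executor invariance) use equality, not
tolerances. These sizes were chosen so the full suite runs in well under
a minute of CPU beyond the pipelines themselves while still exercising
every guarantee; the algorithms have no intrinsic size limits beyond
memory and the quadratic pairwise DP.

## Known limitations

- The built-in aligner is a baseline: representative-guided merging
  discards within-profile evidence, and the NJ guide tree uses a crude
  k-mer distance. For accuracy, wrap a real aligner via
  `cmd:<template>`.
- Separation quality degrades with sparse constraints: species with no
  nearby constraint get whole-flank separations, which grow blocks until
  truncation voids the independence guarantee at that boundary.
- The executor is intra-process; it deliberately does not checkpoint,
  restart, or distribute across hosts.
- Rearrangements and inversions are out of scope: the constraint order
  assumes colinear sequences.
- The stage DP requires strictly binary rooted trees with branch
  lengths.
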