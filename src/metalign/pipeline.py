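"""Combined depth-wise + length-wise pipeline.

For very long and very deep problems the two partitioners compose: the
tree is cut into sub-trees, and every sub-tree alignment problem is
itself broken length-wise into blocks. Each sub-tree job therefore
spawns its own set of parallel block jobs — a two-level dynamic job
hierarchy.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .aligners import AlignerBackend
from .constraints import generate_anchor_constraints
from .crumble import crumble_align
from .executor import ExecutorConfig
from .msa import MultipleAlignment, SequenceRecord


class CrumbleBackend(AlignerBackend):
    """A backend that partitions each problem length-wise before aligning.

    Constraints are generated on the fly from unique exact k-mer anchors;
    the inner backend aligns the resulting blocks and separations. Each
    call runs its own executor, so when this backend serves as the
    sub-tree aligner of the depth-wise pipeline, sub-tree jobs spawn
    their own parallel block jobs.
    """

    def __init__(
        self,
        inner: AlignerBackend,
        core_size: int,
        max_block_size: Optional[int] = None,
        kmer: int = 12,
        executor: Optional[ExecutorConfig] = None,
    ) -> None:
        self.inner = inner
        self.core_size = core_size
        self.max_block_size = max_block_size
        self.kmer = kmer
        self.executor = executor or ExecutorConfig(jobs=1)
        self.name = f"crumble({inner.name})"

    def _align(
        self,
        seqs: Sequence[SequenceRecord],
        guide_tree,
    ) -> MultipleAlignment:
        cs = generate_anchor_constraints(seqs, self.kmer)
        return crumble_align(
            seqs,
            cs,
            self.inner,
            self.core_size,
            self.max_block_size,
            executor=self.executor,
        )
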