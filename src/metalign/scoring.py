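"""The average agreement score between two multiple alignments.

For a species pair (X, Y), an alignment induces a list of pairwise
events: residue i of X aligned to residue j of Y, residue i of X aligned
to a gap, or a gap aligned to residue j of Y (columns gapped in both are
dropped). The pairwise agreement of a prediction against a truth
alignment is the fraction of the *predicted* events that also occur in
the truth — identical alignments score 1, alignments sharing no event
score 0 — and the overall score averages the pairwise scores over all
species pairs, or over a random sample of pairs for very deep problems.
"""

from __future__ import annotations

from itertools import combinations
from typing import Optional

import numpy as np

from .errors import InvalidInputError
from .msa import GAP, MultipleAlignment

# an event is (i, j) with None on the gap side
Event = tuple[Optional[int], Optional[int]]


def project_pair(aln: MultipleAlignment, x: str, y: str) -> list[Event]:
    """Pairwise projection of rows ``x`` and ``y``: ordered event list."""
    row_x, row_y = aln.row(x), aln.row(y)
    events: list[Event] = []
    i = j = 0
    for cx, cy in zip(row_x, row_y):
        gx, gy = cx == GAP, cy == GAP
        if gx and gy:
            continue
        if gx:
            events.append((None, j))
            j += 1
        elif gy:
            events.append((i, None))
            i += 1
        else:
            events.append((i, j))
            i += 1
            j += 1
    return events


def pairwise_agreement(
    pred: MultipleAlignment, truth: MultipleAlignment, x: str, y: str
) -> float:
    """Fraction of predicted events for (x, y) present in the truth."""
    pred_events = project_pair(pred, x, y)
    if not pred_events:
        return 1.0
    truth_events = set(project_pair(truth, x, y))
    hits = sum(1 for e in pred_events if e in truth_events)
    return hits / len(pred_events)


def agreement(
    pred: MultipleAlignment,
    truth: MultipleAlignment,
    sample_pairs: Optional[int] = None,
    seed: Optional[int] = None,
) -> float:
    """Average agreement of ``pred`` against ``truth`` over species pairs.

    Both alignments must carry the same row names and identical row
    projections. With ``sample_pairs``, that many distinct pairs are
    sampled uniformly without replacement using ``seed``.
    """
    names = sorted(pred.names)
    if names != sorted(truth.names):
        raise InvalidInputError("alignments have different row names")
    for n in names:
        if pred.projection(n) != truth.projection(n):
            raise InvalidInputError(
                f"row {n!r} projects differently in the two alignments"
            )
    if len(names) < 2:
        raise InvalidInputError("need at least two rows to score")
    pairs = list(combinations(names, 2))
    if sample_pairs is not None and sample_pairs < len(pairs):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=sample_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
    scores = [pairwise_agreement(pred, truth, x, y) for x, y in pairs]
    return float(sum(scores) / len(scores))
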