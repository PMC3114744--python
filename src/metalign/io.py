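"""File formats: FASTA, aligned FASTA, MAF, Newick, and key=value config.

Internally everything is 0-based with half-open intervals; MAF's
conventions (0-based start, source size, strand) are applied only at the
writer boundary. Readers are strict: they reject what the writers never
produce.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .errors import FormatError, InvalidInputError
from .msa import DNA_ALPHABET, GAP, MultipleAlignment, SequenceRecord
from .tree import PhyloTree, TreeNode

PathLike = Union[str, Path]
_WRAP = 60


def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Unaligned FASTA: case-normalised to upper, '-' stripped, names unique."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in seen:
            raise FormatError(f"duplicate sequence name {name!r} in {path}")
        seen.add(name)
        residues = str(rec.seq).upper().replace(GAP, "")
        bad = set(residues) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"non-DNA characters {sorted(bad)} in sequence {name!r} ({path})"
            )
        records.append(SequenceRecord(name, residues))
    if not records:
        raise FormatError(f"no sequences in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: PathLike) -> None:
    bio = [
        BioSeqRecord(Seq(r.residues), id=r.name, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=_WRAP)
        writer.write_file(bio)


def read_alignment(path: PathLike) -> MultipleAlignment:
    """Aligned FASTA: rows must be equal length; all-gap columns dropped."""
    names, rows, seen = [], [], set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate row name {rec.id!r} in {path}")
        seen.add(rec.id)
        names.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not names:
        raise FormatError(f"no rows in {path}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise FormatError(f"ragged alignment in {path}: row lengths {sorted(lengths)}")
    try:
        aln = MultipleAlignment(names, rows)
    except InvalidInputError as exc:
        raise FormatError(str(exc)) from exc
    return aln.drop_all_gap_columns()


def write_alignment(
    aln: MultipleAlignment, path: PathLike, format: str = "afa"
) -> None:
    """Write aligned FASTA (``afa``) or a single-block MAF (``maf``)."""
    if format == "afa":
        bio = [
            BioSeqRecord(Seq(aln.row(n)), id=n, description="") for n in aln.names
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=_WRAP)
            writer.write_file(bio)
    elif format == "maf":
        with open(path, "w") as fh:
            fh.write("##maf version=1\n")
            fh.write("a score=0.0\n")
            name_w = max((len(n) for n in aln.names), default=0)
            for n in aln.names:
                row = aln.row(n)
                size = len(row) - row.count(GAP)
                fh.write(
                    f"s {n:<{name_w}} 0 {size} + {size} {row}\n"
                )
            fh.write("\n")
    else:
        raise InvalidInputError(f"unknown alignment format {format!r}")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def read_newick(path: PathLike) -> PhyloTree:
    """Rooted binary Newick with branch lengths; polytomies are rejected
    (resolve them upstream)."""
    try:
        dtree = dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise FormatError(f"cannot parse Newick in {path}: {exc}") from exc

    def convert(dnode) -> TreeNode:
        children = dnode.child_nodes()
        if len(children) == 0:
            if dnode.taxon is None:
                raise FormatError(f"unnamed leaf in {path}")
            node = TreeNode(name=dnode.taxon.label.replace(" ", "_"))
        elif len(children) == 2:
            node = TreeNode(left=convert(children[0]), right=convert(children[1]))
        else:
            raise InvalidInputError(
                f"polytomy ({len(children)} children) in {path}; "
                "resolve polytomies before loading"
            )
        if dnode.parent_node is not None:
            if dnode.edge.length is None:
                raise FormatError(f"missing branch length in {path}")
            node.length = float(dnode.edge.length)
        return node

    root = convert(dtree.seed_node)
    return PhyloTree(root)


def write_newick(tree: PhyloTree, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def parse_newick_string(text: str) -> PhyloTree:
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".nwk", delete=False) as fh:
        fh.write(text)
        name = fh.name
    try:
        return read_newick(name)
    finally:
        Path(name).unlink(missing_ok=True)


# ---------------------------------------------------------------------------
# key=value config files mirroring the CLI flags
# ---------------------------------------------------------------------------


def read_config(path: PathLike) -> dict[str, str]:
    """Simple ``key = value`` file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected key=value")
            key, value = line.split("=", 1)
            out[key.strip().replace("_", "-")] = value.strip()
    return out
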