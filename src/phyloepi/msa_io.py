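"""Reading, validating, concatenating and writing multiple sequence alignments.

The central container is :class:`AlignedSeqSet`: N equal-length uppercase
nucleotide sequences over ``{A,C,G,T,N,-}`` with unique taxon labels. It is the
shared coordinate frame for everything downstream — CpG site scanning, binary
recoding and distance computation all index into its columns. Coordinates are
0-based and half-open; a dinucleotide site starting at column ``i`` occupies
columns ``[i, i+2)``.

Alignments assembled from several homologous blocks (e.g. a handful of promoter
regions strung together gene by gene) are built with :func:`concat_blocks`,
which matches taxa by label — never by record position — and remembers the
block boundaries.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentFormatError,
    AlignmentShapeError,
    AlphabetError,
    ConcatenationError,
    DuplicateLabelError,
)

#: Permitted residue characters. ``N`` is the only ambiguity code accepted;
#: other IUPAC codes are rejected at read time rather than silently coerced,
#: because a coerced base could fabricate or destroy a CpG call. The gap
#: character is ``-`` only ('.' is rejected for the same reason).
ALPHABET = frozenset("ACGTN-")

#: Characters treated as missing data in site classification and distances.
GAP_CHARS = frozenset("N-")


@dataclass(frozen=True)
class AlignedSeqSet:
    """An immutable, validated multiple sequence alignment.

    Parameters
    ----------
    labels
        Unique, nonempty taxon names, in input order.
    rows
        One sequence per taxon, equal lengths, alphabet ``{A,C,G,T,N,-}``.
        Lowercase input is folded to uppercase.
    block_boundaries
        Cumulative column offsets of concatenated blocks, starting with 0 and
        ending with the alignment length. Metadata only: it does not take part
        in equality, and a plain alignment has the single block ``(0, L)``.
    """

    labels: tuple[str, ...]
    rows: tuple[str, ...]
    block_boundaries: tuple[int, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        labels = tuple(str(l) for l in self.labels)
        rows = tuple(str(r).upper() for r in self.rows)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "rows", rows)
        if len(labels) != len(rows):
            raise AlignmentShapeError(
                f"{len(labels)} labels but {len(rows)} sequences"
            )
        if len(rows) < 2:
            raise AlignmentShapeError("an alignment needs at least 2 sequences")
        if any(not l for l in labels):
            raise DuplicateLabelError("empty taxon label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise DuplicateLabelError(f"duplicate taxon labels: {dupes}")
        length = len(rows[0])
        for lab, row in zip(labels, rows):
            if len(row) != length:
                raise AlignmentShapeError(
                    f"row {lab!r} has length {len(row)}, expected {length}"
                )
            bad = set(row) - ALPHABET
            if bad:
                raise AlphabetError(
                    f"row {lab!r} contains characters outside ACGTN-: {sorted(bad)}"
                )
        if length < 2:
            raise AlignmentShapeError("alignment must have at least 2 columns")
        if not self.block_boundaries:
            object.__setattr__(self, "block_boundaries", (0, length))
        else:
            bb = tuple(int(b) for b in self.block_boundaries)
            if bb[0] != 0 or bb[-1] != length or list(bb) != sorted(set(bb)):
                raise AlignmentShapeError(
                    f"invalid block boundaries {bb} for length {length}"
                )
            object.__setattr__(self, "block_boundaries", bb)

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.rows[0])

    def row(self, label: str) -> str:
        """Sequence of taxon *label*."""
        try:
            return self.rows[self.labels.index(label)]
        except ValueError:
            raise KeyError(label) from None

    def reorder(self, labels: "list[str] | tuple[str, ...]") -> "AlignedSeqSet":
        """Return the same alignment with taxa in the given label order."""
        rows = tuple(self.row(l) for l in labels)
        return AlignedSeqSet(tuple(labels), rows, self.block_boundaries)


def read_alignment(path: "str | os.PathLike", format: str = "fasta") -> AlignedSeqSet:
    """Read an aligned FASTA file into a validated :class:`AlignedSeqSet`.

    Record order is preserved. Raises :class:`AlignmentFormatError` on an
    empty/unparsable file, :class:`AlignmentShapeError` on unequal row lengths
    and :class:`DuplicateLabelError` on repeated record ids.
    """
    try:
        records = list(SeqIO.parse(os.fspath(path), format))
    except (ValueError, FileNotFoundError) as exc:
        if isinstance(exc, FileNotFoundError):
            raise
        raise AlignmentFormatError(f"cannot parse {path}: {exc}") from exc
    if not records:
        raise AlignmentFormatError(f"no sequence records found in {path}")
    labels = tuple(rec.id for rec in records)
    rows = tuple(str(rec.seq) for rec in records)
    return AlignedSeqSet(labels, rows)


def write_alignment(aln: AlignedSeqSet, path: "str | os.PathLike") -> None:
    """Write *aln* as aligned FASTA; ``read_alignment(write(x)) == x``."""
    records = [
        SeqRecord(Seq(row), id=lab, description="")
        for lab, row in zip(aln.labels, aln.rows)
    ]
    SeqIO.write(records, os.fspath(path), "fasta")


def concat_blocks(blocks: "list[AlignedSeqSet]") -> AlignedSeqSet:
    """Concatenate aligned blocks column-wise, matching taxa by label.

    All blocks must carry the identical label *set*; row order follows the
    first block. The returned alignment records the cumulative block offsets
    in ``block_boundaries``. Single-block input is returned as-is.
    """
    if not blocks:
        raise ConcatenationError("no blocks to concatenate")
    if len(blocks) == 1:
        return blocks[0]
    ref = blocks[0]
    ref_set = set(ref.labels)
    for k, blk in enumerate(blocks[1:], start=2):
        if set(blk.labels) != ref_set:
            raise ConcatenationError(
                f"block {k} labels {sorted(set(blk.labels))} != "
                f"block 1 labels {sorted(ref_set)}"
            )
    rows = tuple(
        "".join(blk.row(lab) for blk in blocks) for lab in ref.labels
    )
    boundaries = [0]
    for blk in blocks:
        boundaries.append(boundaries[-1] + blk.length)
    return AlignedSeqSet(ref.labels, rows, tuple(boundaries))
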