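"""Alt-allele read filtering on top of the range join.

The showcase query these filters implement: among reads that align to the
reference with matches/mismatches only (an all-``M`` CIGAR), which ones
overlap a known variant site *and* carry the alternate allele there?

An all-M alignment maps read offsets to reference positions linearly, so
for a variant at reference position ``pos`` covered by a read starting at
``read.pos`` the variant's bases sit at read offset ``pos - read.pos``.
The allele check is a substring comparison at that offset:
case-insensitive, with ``N`` in the read never matching, and alleles
running past the read end counting as absent rather than erroring.  Reads
with indels or clipping are excluded outright — no realignment is
attempted, so the coordinate map stays trivial.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .tables import GenomicTable, reference_span
from .rangejoin import join_pairs

__all__ = [
    "AlignedReadView",
    "VariantView",
    "cigar_is_all_match",
    "sequence_contains_at",
    "read_contains_alt",
    "alt_supporting_reads",
]

_ALL_M_RE = re.compile(r"^(?:\d+M)+$")
_CIGAR_OK_RE = re.compile(r"^(?:\d+[MIDNSHP=X])+$")


@dataclass(frozen=True)
class AlignedReadView:
    """The slice of an aligned read the allele filter needs."""

    chrom: str
    pos: int  # 1-based leftmost mapped position
    cigar: str
    seq: str


@dataclass(frozen=True)
class VariantView:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str


def cigar_is_all_match(cigar: str) -> bool:
    """True iff every CIGAR operation is M (alignment has no indels/clips)."""
    if not _CIGAR_OK_RE.match(cigar):
        raise ValueError(f"unparseable CIGAR {cigar!r}")
    return _ALL_M_RE.match(cigar) is not None


def sequence_contains_at(seq: str, offset: int, sub: str) -> bool:
    """Does ``sub`` occur in ``seq`` at 0-based ``offset``?

    Case-insensitive; an ``N`` base in ``seq`` matches nothing; offsets
    outside the sequence (or substrings running past its end) are False.
    """
    if offset < 0 or offset + len(sub) > len(seq):
        return False
    window = seq[offset:offset + len(sub)].upper()
    if "N" in window:
        return False
    return window == sub.upper()


def read_contains_alt(read: AlignedReadView, v: VariantView) -> bool:
    """Does an all-M read carry the variant's alternate allele?

    Requires ``cigar_is_all_match(read.cigar)`` and matching chromosomes;
    violating either is a caller bug and raises.
    """
    if read.chrom != v.chrom:
        raise ValueError(
            f"read on {read.chrom!r} vs variant on {v.chrom!r}: "
            "caller must join on chromosome first"
        )
    if not cigar_is_all_match(read.cigar):
        raise ValueError(
            f"read CIGAR {read.cigar!r} is not all-M: filter CIGARs before "
            "the allele check"
        )
    if len(read.seq) != reference_span(read.cigar):
        raise ValueError(
            f"sequence length {len(read.seq)} does not match CIGAR "
            f"{read.cigar!r}"
        )
    return sequence_contains_at(read.seq, v.pos - read.pos, v.alt)


def alt_supporting_reads(
    reads: GenomicTable,
    variants: GenomicTable,
    partitions: int = 1,
) -> GenomicTable:
    """Range-join reads with variants, keep alt-carrying all-M overlaps.

    ``reads`` and ``variants`` are the tables produced by
    :func:`gjoin.tables.read_sam` and :func:`gjoin.tables.read_vcf` (or
    simulated equivalents with the same columns).  The result is the join
    result restricted to pairs where the read aligns with an all-M CIGAR
    and carries the variant's ALT allele at the variant position; one row
    per qualifying (read, variant) pair, read columns first.
    """
    for table, cols in ((reads, ("chrom", "pos", "cigar", "seq")),
                        (variants, ("chrom", "pos", "ref", "alt"))):
        for col in cols:
            table.schema.index_of(col)  # raises KeyError if missing

    r_chrom = reads.schema.index_of("chrom")
    r_pos = reads.schema.index_of("pos")
    r_cigar = reads.schema.index_of("cigar")
    r_seq = reads.schema.index_of("seq")
    v_chrom = variants.schema.index_of("chrom")
    v_pos = variants.schema.index_of("pos")
    v_ref = variants.schema.index_of("ref")
    v_alt = variants.schema.index_of("alt")

    pairs = join_pairs(reads, variants, partitions=partitions)
    kept = []
    for i, j in pairs:
        read_row = reads.rows[i]
        var_row = variants.rows[j]
        if not cigar_is_all_match(read_row[r_cigar]):
            continue
        view = AlignedReadView(
            chrom=read_row[r_chrom], pos=read_row[r_pos],
            cigar=read_row[r_cigar], seq=read_row[r_seq],
        )
        variant = VariantView(
            chrom=var_row[v_chrom], pos=var_row[v_pos],
            ref=var_row[v_ref], alt=var_row[v_alt],
        )
        if read_contains_alt(view, variant):
            kept.append((i, j))

    from .rangejoin import _concat_schema  # deliberate: same schema as range_join

    kept.sort(key=lambda p: (p[1], p[0]))
    return GenomicTable(
        name=f"{reads.name}_alt_supporting",
        schema=_concat_schema(reads, variants),
        rows=[tuple(reads.rows[i]) + tuple(variants.rows[j]) for i, j in kept],
    )
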