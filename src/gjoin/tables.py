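"""Schema-bearing genomic tables and readers for standard formats.

A :class:`GenomicTable` is an ordered collection of typed tuples plus a
:class:`Schema`; when the schema declares an *interval key* — the names of
its (chromosome, start, end) columns — the table can act as either side of
a range join.

Every reader normalizes coordinates to the internal convention — 1-based,
closed on both ends — at the boundary:

============  ===========================  ==========================
format        native convention            conversion applied
============  ===========================  ==========================
BED           0-based half-open            start+1, end unchanged
VCF           1-based POS                  end = POS + len(REF) - 1
SAM           1-based POS                  end = POS + ref span - 1
GFF3          1-based closed               none
TSV           declared by caller           optional half-open shift
============  ===========================  ==========================

Rows a reader cannot accept (malformed coordinates, unmapped reads, ``*``
CIGARs) are never silently dropped: they are counted in the table's
``skipped`` report.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from typing import Any, Dict, Iterable, List, Optional, Sequence, Tuple

import cyvcf2
import pandas as pd
import pysam

from .intervals import GenomicInterval

__all__ = [
    "Schema",
    "IntervalKey",
    "GenomicTable",
    "read_bed",
    "read_vcf",
    "read_sam",
    "read_gff",
    "read_tsv",
    "write_tsv",
    "reference_span",
]

_TYPES = {"string": str, "integer": int, "float": float}


@dataclass(frozen=True)
class IntervalKey:
    """Names of the (chrom, start, end) columns forming a table's join key."""

    chrom: str
    start: str
    end: str


@dataclass
class Schema:
    columns: List[Tuple[str, str]]  # (name, one of {"string","integer","float"})
    interval_key: Optional[IntervalKey] = None

    def __post_init__(self) -> None:
        names = [n for n, _ in self.columns]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate column names in schema: {names}")
        for name, typ in self.columns:
            if typ not in _TYPES:
                raise ValueError(f"unknown column type {typ!r} for {name!r}")
        if self.interval_key is not None:
            idx = {n: t for n, t in self.columns}
            for col, want in (
                (self.interval_key.chrom, "string"),
                (self.interval_key.start, "integer"),
                (self.interval_key.end, "integer"),
            ):
                if col not in idx:
                    raise ValueError(f"interval-key column {col!r} not in schema")
                if idx[col] != want:
                    raise ValueError(
                        f"interval-key column {col!r} must be {want}, is {idx[col]}"
                    )

    def names(self) -> List[str]:
        return [n for n, _ in self.columns]

    def index_of(self, name: str) -> int:
        try:
            return self.names().index(name)
        except ValueError:
            raise KeyError(f"no column named {name!r}") from None


@dataclass
class GenomicTable:
    name: str
    schema: Schema
    rows: List[tuple] = field(default_factory=list)
    #: reason -> number of input records rejected during reading
    skipped: Dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)

    def column(self, name: str) -> list:
        i = self.schema.index_of(name)
        return [row[i] for row in self.rows]

    def interval_of(self, row: tuple) -> GenomicInterval:
        key = self.schema.interval_key
        if key is None:
            raise ValueError(f"table {self.name!r} has no interval key")
        s = self.schema
        return GenomicInterval(
            chrom=row[s.index_of(key.chrom)],
            start=row[s.index_of(key.start)],
            end=row[s.index_of(key.end)],
        )

    def intervals(self) -> List[GenomicInterval]:
        return [self.interval_of(r) for r in self.rows]

    def validate(self) -> None:
        """Check row arity, declared types and start<=end; raise on violation."""
        types = [_TYPES[t] for _, t in self.schema.columns]
        for i, row in enumerate(self.rows):
            if len(row) != len(types):
                raise ValueError(
                    f"row {i} of {self.name!r} has {len(row)} fields, "
                    f"schema has {len(types)}"
                )
            for value, typ, (name, _) in zip(row, types, self.schema.columns):
                if value is not None and not isinstance(value, typ):
                    raise TypeError(
                        f"row {i} column {name!r}: {value!r} is not {typ.__name__}"
                    )
            if self.schema.interval_key is not None:
                iv = self.interval_of(row)  # raises if start > end
                del iv

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.schema.names())


def _normalize_chrom(chrom: str, mode: Optional[str]) -> str:
    if mode is None:
        return chrom
    if mode == "strip":
        return chrom[3:] if chrom.startswith("chr") else chrom
    if mode == "add":
        return chrom if chrom.startswith("chr") else "chr" + chrom
    raise ValueError(f"unknown chromosome normalization mode {mode!r}")


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_bed(path: str, chr_normalize: Optional[str] = None) -> GenomicTable:
    """Read BED3+ into a table named after the file.

    BED's 0-based half-open ``[chromStart, chromEnd)`` becomes 1-based
    closed ``[chromStart+1, chromEnd]``.  ``browser``/``track``/comment
    lines are skipped; rows with ``chromEnd <= chromStart`` are rejected
    into the skip report.
    """
    schema = Schema(
        columns=[("chrom", "string"), ("start", "integer"), ("end", "integer"),
                 ("name", "string")],
        interval_key=IntervalKey("chrom", "start", "end"),
    )
    table = GenomicTable(name="bed", schema=schema)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "browser", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: BED line has {len(fields)} fields, need >= 3"
                )
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer BED coordinates"
                ) from None
            if end0 <= start0:
                table.skipped["empty_or_inverted_interval"] = (
                    table.skipped.get("empty_or_inverted_interval", 0) + 1
                )
                continue
            chrom = _normalize_chrom(fields[0], chr_normalize)
            name = fields[3] if len(fields) > 3 else ""
            table.rows.append((chrom, start0 + 1, end0, name))
    return table


def read_vcf(path: str, chr_normalize: Optional[str] = None) -> GenomicTable:
    """Read a VCF (optionally gzipped) with one row per ALT allele.

    Multi-allelic records are expanded so each ALT gets its own row; the
    interval is the reference footprint ``[POS, POS + len(REF) - 1]``.
    """
    schema = Schema(
        columns=[("chrom", "string"), ("pos", "integer"), ("end", "integer"),
                 ("id", "string"), ("ref", "string"), ("alt", "string")],
        interval_key=IntervalKey("chrom", "pos", "end"),
    )
    table = GenomicTable(name="variants", schema=schema)
    for rec in cyvcf2.VCF(path):
        chrom = _normalize_chrom(rec.CHROM, chr_normalize)
        pos = rec.POS
        end = pos + len(rec.REF) - 1
        vid = rec.ID or "."
        alts = rec.ALT or []
        if not alts:
            table.skipped["no_alt_allele"] = table.skipped.get("no_alt_allele", 0) + 1
            continue
        for alt in alts:
            table.rows.append((chrom, pos, end, vid, rec.REF, alt))
    return table


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
#: CIGAR operations that consume reference positions
_REF_OPS = frozenset("MDN=X")


def reference_span(cigar: str) -> int:
    """Number of reference positions an alignment with this CIGAR covers.

    Sums the lengths of M/D/N/=/X operations; insertions and clips consume
    no reference.  Raises :class:`ValueError` on an unparseable CIGAR.
    """
    if not cigar or cigar == "*":
        raise ValueError(f"cannot compute reference span of CIGAR {cigar!r}")
    pos = 0
    total = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise ValueError(f"malformed CIGAR {cigar!r}")
        pos = m.end()
        if m.group(2) in _REF_OPS:
            total += int(m.group(1))
    if pos != len(cigar):
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return total


def read_sam(path: str, chr_normalize: Optional[str] = None) -> GenomicTable:
    """Read mapped primary alignments from SAM/BAM.

    Unmapped, secondary (0x100) and supplementary (0x800) records, and
    mapped records with a ``*`` CIGAR, are excluded and tallied in the
    skip report.  The interval is ``[POS, POS + reference_span(CIGAR) - 1]``.
    """
    schema = Schema(
        columns=[("qname", "string"), ("chrom", "string"), ("pos", "integer"),
                 ("end", "integer"), ("cigar", "string"), ("seq", "string"),
                 ("mapq", "integer"), ("flag", "integer")],
        interval_key=IntervalKey("chrom", "pos", "end"),
    )
    table = GenomicTable(name="reads", schema=schema)

    def skip(reason: str) -> None:
        table.skipped[reason] = table.skipped.get(reason, 0) + 1

    with pysam.AlignmentFile(path, require_index=False, check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped:
                skip("unmapped")
                continue
            if rec.is_secondary or rec.is_supplementary:
                skip("secondary_or_supplementary")
                continue
            cigar = rec.cigarstring
            if not cigar:
                skip("missing_cigar")
                continue
            pos = rec.reference_start + 1  # pysam is 0-based
            chrom = _normalize_chrom(rec.reference_name, chr_normalize)
            end = pos + reference_span(cigar) - 1
            table.rows.append(
                (rec.query_name, chrom, pos, end, cigar,
                 rec.query_sequence or "", rec.mapping_quality, rec.flag)
            )
    return table


def read_gff(path: str, chr_normalize: Optional[str] = None) -> GenomicTable:
    """Read GFF3 (1-based closed already; no coordinate shift).

    The attributes column is kept as its raw string.
    """
    schema = Schema(
        columns=[("chrom", "string"), ("source", "string"), ("feature", "string"),
                 ("start", "integer"), ("end", "integer"), ("score", "string"),
                 ("strand", "string"), ("attributes", "string")],
        interval_key=IntervalKey("chrom", "start", "end"),
    )
    table = GenomicTable(name="gff", schema=schema)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(
                    f"{path}:{lineno}: GFF line has {len(fields)} fields, need >= 8"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer GFF coordinates"
                ) from None
            if start > end:
                table.skipped["inverted_interval"] = (
                    table.skipped.get("inverted_interval", 0) + 1
                )
                continue
            attributes = fields[8] if len(fields) > 8 else ""
            table.rows.append(
                (_normalize_chrom(fields[0], chr_normalize), fields[1], fields[2],
                 start, end, fields[5], fields[6], attributes)
            )
    return table


def read_tsv(
    path: str,
    interval_key: Optional[Tuple[str, str, str]] = None,
    zero_based_half_open: bool = False,
    chr_normalize: Optional[str] = None,
    name: Optional[str] = None,
) -> GenomicTable:
    """Read a header-bearing TSV with inferred column types.

    Columns whose values all parse as integers become integer columns,
    then float, else string.  ``interval_key`` names the (chrom, start,
    end) columns; coordinates are assumed 1-based closed unless
    ``zero_based_half_open`` is set, in which case the BED shift is applied.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    columns: List[Tuple[str, str]] = []
    converted: Dict[str, list] = {}
    for col in df.columns:
        values = df[col].tolist()
        for typ_name, typ in (("integer", int), ("float", float)):
            try:
                converted[col] = [typ(v) for v in values]
                columns.append((col, typ_name))
                break
            except ValueError:
                continue
        else:
            converted[col] = values
            columns.append((col, "string"))
    key = None
    if interval_key is not None:
        chrom_c, start_c, end_c = interval_key
        if zero_based_half_open:
            converted[start_c] = [v + 1 for v in converted[start_c]]
        if chr_normalize is not None:
            converted[chrom_c] = [
                _normalize_chrom(v, chr_normalize) for v in converted[chrom_c]
            ]
        key = IntervalKey(chrom_c, start_c, end_c)
    schema = Schema(columns=columns, interval_key=key)
    names = [c for c, _ in columns]
    rows = list(zip(*(converted[c] for c in names))) if len(df) else []
    table = GenomicTable(name=name or "tsv", schema=schema, rows=[tuple(r) for r in rows])
    table.validate()
    return table


def write_tsv(table: GenomicTable, path: str) -> None:
    """Write the table as TSV: a header of column names, then one line per row."""
    with open(path, "wt") as fh:
        fh.write("\t".join(table.schema.names()) + "\n")
        for row in table.rows:
            fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")
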