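"""Synthetic genomic tables with planted ground truth, plus join oracles.

Everything in this package is testable offline: :func:`simulate_tables`
emulates a desk-scale slice of a resequencing study — uniform-start,
fixed-length aligned reads; SNV-style variant sites (a tenth with
multi-base alternate alleles); non-overlapping gene annotations — and
records exactly which (read, variant) overlaps it planted and which of
those reads carry the alternate allele.  Variant sites are spaced more
than a read length apart, and background reads are placed outside every
variant's footprint, so the planted pairs are *all* the overlapping pairs:
any discrepancy between engine output and truth is an engine bug, not a
generator accident.

Two independent reference implementations of the join live here as test
oracles: :func:`brute_force_join`, the cross-product overlap filter the
tree-based engine is measured against, and
:func:`sweep_line_pair_count`, a separately-coded plane-sweep counter used
to cross-check the brute force itself.

What the generator does **not** emulate: sequencing error, base
qualities, indel alignments over variant sites, coverage biases, or
multi-sample genotypes.  Tests passing on these tables demonstrate the
relational/interval machinery, not variant-calling accuracy on real data.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .tables import GenomicTable, IntervalKey, Schema

__all__ = [
    "SimConfig",
    "SimResult",
    "PlantedPair",
    "simulate_tables",
    "brute_force_join",
    "sweep_line_pair_count",
    "worked_example_fixtures",
    "write_sam",
    "write_vcf",
    "write_gff",
    "write_truth",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    ``overlap_fraction`` is the fraction of reads planted over a variant
    site; ``alt_carrier_fraction`` the fraction of those carrying the
    alternate allele.  Defaults describe a small three-chromosome genome
    with 100 bp reads at desk scale.
    """

    seed: int = 0
    chroms: Tuple[Tuple[str, int], ...] = (
        ("chr1", 1_000_000),
        ("chr2", 800_000),
        ("chr3", 600_000),
    )
    n_reads: int = 2_000
    read_length: int = 100
    n_variants: int = 200
    n_annotations: int = 50
    overlap_fraction: float = 0.3
    alt_carrier_fraction: float = 0.2

    def __post_init__(self) -> None:
        for frac, name in ((self.overlap_fraction, "overlap_fraction"),
                           (self.alt_carrier_fraction, "alt_carrier_fraction")):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        if not self.chroms:
            raise ValueError("at least one chromosome is required")
        for name, length in self.chroms:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        for count, name in ((self.n_reads, "n_reads"),
                            (self.n_variants, "n_variants"),
                            (self.n_annotations, "n_annotations")):
            if count < 0:
                raise ValueError(f"{name} must be >= 0, got {count}")
        if self.read_length < 4:
            raise ValueError("read_length must be >= 4")


@dataclass(frozen=True)
class PlantedPair:
    read_rowid: int
    variant_rowid: int
    carries_alt: bool


@dataclass
class SimResult:
    reads: GenomicTable
    variants: GenomicTable
    annotations: GenomicTable
    truth: List[PlantedPair] = field(default_factory=list)


_READS_SCHEMA = Schema(
    columns=[("qname", "string"), ("chrom", "string"), ("pos", "integer"),
             ("end", "integer"), ("cigar", "string"), ("seq", "string"),
             ("mapq", "integer"), ("flag", "integer")],
    interval_key=IntervalKey("chrom", "pos", "end"),
)
_VARIANTS_SCHEMA = Schema(
    columns=[("chrom", "string"), ("pos", "integer"), ("end", "integer"),
             ("id", "string"), ("ref", "string"), ("alt", "string")],
    interval_key=IntervalKey("chrom", "pos", "end"),
)
_ANNOTATIONS_SCHEMA = Schema(
    columns=[("chrom", "string"), ("start", "integer"), ("end", "integer"),
             ("gene_id", "string"), ("strand", "string")],
    interval_key=IntervalKey("chrom", "start", "end"),
)


def _allocate(total: int, weights: Sequence[int], rng: np.random.Generator) -> List[int]:
    """Split `total` items over chromosomes roughly proportional to length."""
    weights = np.asarray(weights, dtype=float)
    probs = weights / weights.sum()
    counts = rng.multinomial(total, probs)
    return counts.tolist()


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_tables(cfg: SimConfig) -> SimResult:
    """Generate reads, variants and annotations with planted truth.

    Deterministic for a fixed config (single numpy Generator seeded from
    ``cfg.seed``).  The planted (read, variant) pairs are exactly the
    overlapping pairs of the two tables, and the achieved overlap fraction
    is ``round(n_reads * overlap_fraction) / n_reads``.
    """
    rng = np.random.default_rng(cfg.seed)
    # sites are spaced so a read can cover at most one; the margin leaves
    # room for multi-base alternate alleles near read ends
    spacing = cfg.read_length + 8

    # --- variant sites -----------------------------------------------------
    variants = GenomicTable(name="variants", schema=_VARIANTS_SCHEMA)
    sites: List[Tuple[str, int, str, str]] = []  # (chrom, pos, ref, alt)
    lengths = [length for _, length in cfg.chroms]
    for (chrom, length), count in zip(
        cfg.chroms, _allocate(cfg.n_variants, lengths, rng)
    ):
        n_slots = max((length - 2 * spacing) // spacing, 0)
        count = min(count, n_slots)
        if count == 0:
            continue
        slots = rng.choice(n_slots, size=count, replace=False)
        for slot in sorted(slots):
            pos = spacing + int(slot) * spacing
            ref = str(rng.choice(_BASES))
            others = [b for b in "ACGT" if b != ref]
            alt = str(rng.choice(others))
            if rng.random() < 0.10:  # multi-base alternate allele
                alt += _random_seq(rng, int(rng.integers(1, 3)))
            sites.append((chrom, pos, ref, alt))
    for k, (chrom, pos, ref, alt) in enumerate(sites):
        variants.rows.append((chrom, pos, pos + len(ref) - 1, f"var{k}", ref, alt))

    # --- reads -------------------------------------------------------------
    reads = GenomicTable(name="reads", schema=_READS_SCHEMA)
    truth: List[PlantedPair] = []
    n_overlap = round(cfg.n_reads * cfg.overlap_fraction) if sites else 0
    n_alt = round(n_overlap * cfg.alt_carrier_fraction)
    L = cfg.read_length
    chrom_len = dict(cfg.chroms)

    for i in range(n_overlap):
        v_idx = int(rng.integers(0, len(sites)))
        chrom, vpos, ref, alt = sites[v_idx]
        carries_alt = i < n_alt
        allele = alt if carries_alt else ref
        # keep the whole allele inside the read: offset in [0, L - len(allele)]
        lo = max(1, vpos - (L - len(allele)))
        hi = min(vpos, chrom_len[chrom] - L + 1)
        start = int(rng.integers(lo, hi + 1))
        offset = vpos - start
        seq = list(_random_seq(rng, L))
        seq[offset:offset + len(allele)] = list(allele)
        reads.rows.append(
            (f"read{i}", chrom, start, start + L - 1, f"{L}M", "".join(seq), 60, 0)
        )
        truth.append(PlantedPair(read_rowid=i, variant_rowid=v_idx,
                                 carries_alt=carries_alt))

    # background reads avoid every variant footprint entirely
    site_pos: Dict[str, np.ndarray] = {}
    for chrom, _ in cfg.chroms:
        site_pos[chrom] = np.array(
            sorted(p for c, p, _, _ in sites if c == chrom), dtype=int
        )
    n_background = cfg.n_reads - n_overlap
    for b, count in zip(
        range(len(cfg.chroms)), _allocate(n_background, lengths, rng)
    ):
        chrom, length = cfg.chroms[b]
        positions = site_pos[chrom]
        placed = 0
        while placed < count:
            start = int(rng.integers(1, max(length - L + 1, 2)))
            # exclusion: a read [start, start+L-1] overlaps a site at p
            # (footprint up to p+2 for multi-base refs) iff start in
            # [p - L + 1, p + 2]; check the nearest site only
            j = int(np.searchsorted(positions, start))
            bad = False
            for k in (j - 1, j):
                if 0 <= k < len(positions):
                    p = int(positions[k])
                    if p - L + 1 <= start <= p + 2:
                        bad = True
                        break
            if bad:
                continue
            if placed % 10 == 0:
                # a slice of background reads gets non-trivial CIGARs so the
                # all-M filter has something to reject
                half = L // 2
                cigar = f"{half}M2I{L - half - 2}M"
                end = start + (L - 2) - 1  # insertion consumes no reference
            else:
                cigar = f"{L}M"
                end = start + L - 1
            reads.rows.append(
                (f"read{len(reads.rows)}", chrom, start, end, cigar,
                 _random_seq(rng, L), 60, 0)
            )
            placed += 1

    # --- annotations: non-overlapping genes with gaps ------------------------
    annotations = GenomicTable(name="genes", schema=_ANNOTATIONS_SCHEMA)
    gene_id = 0
    for (chrom, length), count in zip(
        cfg.chroms, _allocate(cfg.n_annotations, lengths, rng)
    ):
        if count == 0:
            continue
        stride = max(length // (count + 1), 10)
        cursor = 1
        for _ in range(count):
            gene_len = int(rng.integers(stride // 4, max(stride // 2, stride // 4 + 1)))
            start = cursor + int(rng.integers(0, max(stride - gene_len, 1)))
            end = min(start + gene_len - 1, length)
            if start > length:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            annotations.rows.append((chrom, start, end, f"gene{gene_id}", strand))
            gene_id += 1
            cursor += stride

    result = SimResult(reads=reads, variants=variants,
                       annotations=annotations, truth=truth)
    reads.validate()
    variants.validate()
    annotations.validate()
    return result


def brute_force_join(a: GenomicTable, b: GenomicTable) -> List[Tuple[int, int]]:
    """All (a_rowid, b_rowid) pairs whose intervals overlap: the
    cross-product filter baseline.

    Evaluates the closed-overlap predicate over the full cross product of
    same-chromosome rows (vectorized, but exactly the quadratic baseline
    computation).  This is the reference every join test compares against.
    """
    a_iv = a.intervals()
    b_iv = b.intervals()
    a_by_chrom: Dict[str, List[int]] = {}
    b_by_chrom: Dict[str, List[int]] = {}
    for i, iv in enumerate(a_iv):
        a_by_chrom.setdefault(iv.chrom, []).append(i)
    for j, iv in enumerate(b_iv):
        b_by_chrom.setdefault(iv.chrom, []).append(j)
    pairs: List[Tuple[int, int]] = []
    for chrom, a_idx in a_by_chrom.items():
        b_idx = b_by_chrom.get(chrom)
        if not b_idx:
            continue
        a_start = np.array([a_iv[i].start for i in a_idx])
        a_end = np.array([a_iv[i].end for i in a_idx])
        b_start = np.array([b_iv[j].start for j in b_idx])
        b_end = np.array([b_iv[j].end for j in b_idx])
        hit_a, hit_b = np.nonzero(
            (a_start[:, None] <= b_end[None, :])
            & (b_start[None, :] <= a_end[:, None])
        )
        pairs.extend(
            (a_idx[int(ia)], b_idx[int(jb)]) for ia, jb in zip(hit_a, hit_b)
        )
    pairs.sort()
    return pairs


def sweep_line_pair_count(a: GenomicTable, b: GenomicTable) -> int:
    """Number of overlapping (a, b) pairs, by an independent plane sweep.

    Sorts both sides by start per chromosome and sweeps, holding a heap of
    active intervals keyed by end.  Coded separately from both the tree
    engine and the cross-product filter as a second oracle.
    """
    count = 0
    by_chrom: Dict[str, List[Tuple[int, int, int]]] = {}
    for side, table in enumerate((a, b)):
        for iv in table.intervals():
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, side))
    for items in by_chrom.values():
        items.sort()
        active: List[List[Tuple[int, int]]] = [[], []]  # per side: heap of (end, start)
        for start, end, side in items:
            other = 1 - side
            heap = active[other]
            while heap and heap[0][0] < start:
                heapq.heappop(heap)
            count += len(heap)
            heapq.heappush(active[side], (end, start))
    return count


def worked_example_fixtures() -> Dict[str, object]:
    """The textbook two-gene/three-read tables and the five-interval tree.

    Returns a dict with:

    - ``genes``: table A — gene1 chr3 [100, 1000], gene2 chr3 [4000, 5000];
    - ``reads``: table B — read1 chr3 [150, 250], read2 chr4 [3000, 3100],
      read3 chr1 [1000, 1100];
    - ``tree_intervals``: [1,5], [7,15], [16,19], [20,25], [22,28];
    - ``tree_query``: [17, 23];
    - ``tree_query_expected``: {[16,19], [20,25], [22,28]}.

    Joining genes x reads yields exactly one row: gene1 with read1.
    """
    genes = GenomicTable(
        name="genes",
        schema=Schema(
            columns=[("id", "string"), ("chrom", "string"),
                     ("txStart", "integer"), ("txEnd", "integer"),
                     ("function", "string")],
            interval_key=IntervalKey("chrom", "txStart", "txEnd"),
        ),
        rows=[
            ("gene1", "chr3", 100, 1000, "function1"),
            ("gene2", "chr3", 4000, 5000, "function2"),
        ],
    )
    reads = GenomicTable(
        name="reads",
        schema=Schema(
            columns=[("id", "string"), ("chrom", "string"),
                     ("readStart", "integer"), ("readEnd", "integer")],
            interval_key=IntervalKey("chrom", "readStart", "readEnd"),
        ),
        rows=[
            ("read1", "chr3", 150, 250),
            ("read2", "chr4", 3000, 3100),
            ("read3", "chr1", 1000, 1100),
        ],
    )
    genes.validate()
    reads.validate()
    return {
        "genes": genes,
        "reads": reads,
        "tree_intervals": [(1, 5), (7, 15), (16, 19), (20, 25), (22, 28)],
        "tree_query": (17, 23),
        "tree_query_expected": {(16, 19), (20, 25), (22, 28)},
    }


# ---------------------------------------------------------------------------
# Plain-text writers for the simulate CLI (minimal, valid, uncompressed)


def write_sam(reads: GenomicTable, path: str,
              chroms: Sequence[Tuple[str, int]]) -> None:
    """Write the simulated reads as a plain-text SAM with @SQ headers."""
    s = reads.schema
    cols = [s.index_of(c) for c in
            ("qname", "chrom", "pos", "cigar", "seq", "mapq", "flag")]
    with open(path, "wt") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, length in chroms:
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for row in reads.rows:
            qname, chrom, pos, cigar, seq, mapq, flag = (row[i] for i in cols)
            qual = "I" * len(seq)
            fh.write(
                f"{qname}\t{flag}\t{chrom}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t"
                f"{seq}\t{qual}\n"
            )


def write_vcf(variants: GenomicTable, path: str,
              chroms: Sequence[Tuple[str, int]]) -> None:
    """Write the simulated variants as a minimal VCF 4.2 text file."""
    s = variants.schema
    cols = [s.index_of(c) for c in ("chrom", "pos", "id", "ref", "alt")]
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in chroms:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in variants.rows:
            chrom, pos, vid, ref, alt = (row[i] for i in cols)
            fh.write(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\t.\t.\n")


def write_gff(annotations: GenomicTable, path: str) -> None:
    """Write the simulated gene annotations as GFF3."""
    s = annotations.schema
    cols = [s.index_of(c) for c in ("chrom", "start", "end", "gene_id", "strand")]
    with open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for row in annotations.rows:
            chrom, start, end, gene_id, strand = (row[i] for i in cols)
            fh.write(
                f"{chrom}\tsim\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={gene_id}\n"
            )


def write_truth(truth: List[PlantedPair], path: str) -> None:
    """Write planted (read, variant) pairs as TSV."""
    with open(path, "wt") as fh:
        fh.write("read_rowid\tvariant_rowid\tcarries_alt\n")
        for p in truth:
            fh.write(f"{p.read_rowid}\t{p.variant_rowid}\t{int(p.carries_alt)}\n")
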