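"""The four-stage interval-keyed join.

A range join between two genomic tables A (build side, the smaller) and
B (probe side) runs as a broadcast-style pipeline:

1. **index** — assign dense row ids 0..n-1 to A's rows in input order
   (:func:`index_table`, table "A1": rowid -> record);
2. **extract** — project each indexed row to its interval key
   (:func:`extract_interval_keys`, table "A2": interval -> rowid);
3. **broadcast** — build one interval forest over all A2 entries and hand
   it, read-only, to every execution partition (:func:`broadcast_forest`);
4. **lookup + materialize** — stream B in contiguous partitions, probe
   each row's interval against the shared forest to get matching A row
   ids ("T1": B record -> rowid), then equi-join those ids back against
   A1 to emit one output row per overlapping pair ("T").

"Distributed" is modeled as a partitioned-execution contract: the probe
side is split into chunks that are probed independently against the same
immutable forest and concatenated in chunk order, so results never depend
on the partition count.  Inner-join semantics: probe rows with no overlap
partner produce nothing.

The module keeps instrumented counters (overlap-predicate evaluations) so
the tree strategy can be compared with the brute-force cross-product
baseline without wall-clock measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .intervals import (
    GenomicInterval,
    IntervalForest,
    OpCounter,
    build_forest,
    query_forest,
)
from .tables import GenomicTable, IntervalKey, Schema

__all__ = [
    "IndexedTable",
    "IntervalKeyTable",
    "LookupResult",
    "JoinStats",
    "index_table",
    "extract_interval_keys",
    "broadcast_forest",
    "lookup_stage",
    "materialize",
    "range_join",
    "count_overlap_checks",
]


@dataclass
class IndexedTable:
    """A table with dense row ids 0..n-1 assigned in row order (table "A1")."""

    base: GenomicTable

    def record(self, rowid: int) -> tuple:
        return self.base.rows[rowid]

    def __len__(self) -> int:
        return len(self.base)


@dataclass
class IntervalKeyTable:
    """(interval, rowid) pairs, one per indexed row (table "A2")."""

    entries: List[Tuple[GenomicInterval, int]]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class LookupResult:
    """(B record, A rowid) pairs emitted by the probe stage (table "T1")."""

    pairs: List[Tuple[tuple, int]]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class JoinStats:
    """Overlap-predicate evaluation counts for the last join, per strategy."""

    tree_checks: int = 0
    brute_force_checks: int = 0
    nodes_visited: int = 0

    def as_dict(self) -> Dict[str, int]:
        return {
            "tree": self.tree_checks,
            "brute_force": self.brute_force_checks,
            "nodes_visited": self.nodes_visited,
        }


_last_stats = JoinStats()


def count_overlap_checks() -> Dict[str, int]:
    """Counters from the most recent :func:`range_join`.

    ``tree`` is the number of interval-overlap predicate evaluations the
    forest probes performed; ``brute_force`` is the n x m evaluations the
    cross-product filter would perform on the same inputs.
    """
    return _last_stats.as_dict()


def index_table(t: GenomicTable) -> IndexedTable:
    """Stage 1: key each record by its position in input order."""
    return IndexedTable(base=t)


def extract_interval_keys(it: IndexedTable) -> IntervalKeyTable:
    """Stage 2: project each indexed row to (interval key, rowid)."""
    if it.base.schema.interval_key is None:
        raise ValueError(f"table {it.base.name!r} has no interval key")
    return IntervalKeyTable(
        entries=[(it.base.interval_of(row), rowid)
                 for rowid, row in enumerate(it.base.rows)]
    )


def broadcast_forest(k: IntervalKeyTable) -> IntervalForest:
    """Stage 3: build the shared forest over all interval keys.

    The returned forest is the broadcast value: every probe partition reads
    it and none may mutate it.
    """
    return build_forest(k.entries)


def _chunk_bounds(n: int, partitions: int) -> List[Tuple[int, int]]:
    if partitions < 1:
        raise ValueError(f"partitions must be >= 1, got {partitions}")
    size, extra = divmod(n, partitions)
    bounds = []
    start = 0
    for i in range(partitions):
        stop = start + size + (1 if i < extra else 0)
        bounds.append((start, stop))
        start = stop
    return bounds


def _probe_indexed(
    b: GenomicTable,
    forest: IntervalForest,
    partitions: int,
    counter: Optional[OpCounter],
) -> List[Tuple[int, int]]:
    """(b_rowindex, build_rowid) pairs, probe-row major, rowid minor."""
    if b.schema.interval_key is None:
        raise ValueError(f"table {b.name!r} has no interval key")
    pairs: List[Tuple[int, int]] = []
    for start, stop in _chunk_bounds(len(b.rows), partitions):
        for i in range(start, stop):
            hits = query_forest(forest, b.interval_of(b.rows[i]), counter=counter)
            for rowid in sorted(hits):
                pairs.append((i, rowid))
    return pairs


def lookup_stage(
    b: GenomicTable,
    forest: IntervalForest,
    partitions: int = 1,
    counter: Optional[OpCounter] = None,
) -> LookupResult:
    """Stage 4a: probe each B row's interval against the shared forest.

    B is split into ``partitions`` contiguous chunks; each chunk is probed
    independently and outputs are concatenated in chunk order.  A B row
    overlapping k build-side rows yields k pairs (rowid ascending); a row
    with no hits yields none.
    """
    return LookupResult(
        pairs=[(b.rows[i], rowid)
               for i, rowid in _probe_indexed(b, forest, partitions, counter)]
    )


def _concat_schema(a: GenomicTable, b: GenomicTable) -> Schema:
    """A's columns then B's, prefixing with table names on name collision."""
    a_names = set(a.schema.names())
    b_names = set(b.schema.names())
    clash = a_names & b_names
    cols: List[Tuple[str, str]] = []
    for name, typ in a.schema.columns:
        cols.append((f"{a.name}.{name}" if name in clash else name, typ))
    for name, typ in b.schema.columns:
        cols.append((f"{b.name}.{name}" if name in clash else name, typ))
    return Schema(columns=cols, interval_key=None)


def materialize(
    lookup: LookupResult, it: IndexedTable, b: GenomicTable
) -> GenomicTable:
    """Stage 4b: equi-join T1's row ids against A1 to emit the result table.

    Output rows carry the A record's fields followed by the B record's.
    A row id absent from the indexed table signals engine corruption and
    raises, it is never an expected condition.
    """
    n = len(it)
    rows: List[tuple] = []
    for b_record, rowid in lookup.pairs:
        if not (0 <= rowid < n):
            raise RuntimeError(
                f"internal consistency error: dangling rowid {rowid} "
                f"(indexed table has {n} rows)"
            )
        rows.append(tuple(it.record(rowid)) + tuple(b_record))
    return GenomicTable(
        name=f"{it.base.name}_x_{b.name}",
        schema=_concat_schema(it.base, b),
        rows=rows,
    )


def join_pairs(
    a: GenomicTable,
    b: GenomicTable,
    partitions: int = 1,
    build_side: Optional[str] = None,
) -> List[Tuple[int, int]]:
    """Row-id pairs (a_rowid, b_rowid) of all overlapping rows of A x B.

    The forest is built from the side with fewer rows (ties -> left) unless
    ``build_side`` forces ``"left"`` or ``"right"``.  Updates the module
    join counters.
    """
    if a.schema.interval_key is None or b.schema.interval_key is None:
        missing = a.name if a.schema.interval_key is None else b.name
        raise ValueError(f"table {missing!r} has no interval key")
    if build_side is None:
        build_side = "left" if len(a) <= len(b) else "right"
    if build_side not in ("left", "right"):
        raise ValueError(f"build_side must be 'left' or 'right', got {build_side!r}")

    build, probe = (a, b) if build_side == "left" else (b, a)
    counter = OpCounter()
    indexed = index_table(build)
    forest = broadcast_forest(extract_interval_keys(indexed))
    probed = _probe_indexed(probe, forest, partitions, counter)

    global _last_stats
    _last_stats = JoinStats(
        tree_checks=counter.checks,
        brute_force_checks=len(a) * len(b),
        nodes_visited=counter.nodes,
    )

    if build_side == "left":
        return [(rowid, i) for i, rowid in probed]
    return [(i, rowid) for i, rowid in probed]


def range_join(
    a: GenomicTable,
    b: GenomicTable,
    partitions: int = 1,
    build_side: Optional[str] = None,
) -> GenomicTable:
    """Full interval-overlap join of two tables.

    Composes the four stages.  The forest is built from whichever input has
    fewer rows (ties -> the left input) unless ``build_side`` forces it;
    the output schema is always A's columns then B's in query order
    regardless of build side.  Output order is deterministic: probe-row
    major, build-rowid minor; when the build side is flipped this becomes
    left-row major, right-rowid minor either way after reorientation.
    """
    pairs = join_pairs(a, b, partitions=partitions, build_side=build_side)
    pairs.sort(key=lambda p: (p[1], p[0]))  # B-row major, A-rowid minor
    schema = _concat_schema(a, b)
    rows = [tuple(a.rows[i]) + tuple(b.rows[j]) for i, j in pairs]
    return GenomicTable(name=f"{a.name}_x_{b.name}", schema=schema, rows=rows)
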