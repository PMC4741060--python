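# Methods and design notes

## Coordinate model

Everything inside the package uses 1-based, closed intervals; two
intervals overlap iff `max(starts) <= min(ends)` (sharing a single
position counts). Each reader owns the conversion at the boundary: BED's
0-based half-open `[chromStart, chromEnd)` becomes `[chromStart+1,
chromEnd]`; VCF records span the reference footprint `[POS,
POS+len(REF)-1]`; SAM records span `[POS, POS+refspan(CIGAR)-1]` where
`refspan` sums M/D/N/=/X operation lengths; GFF3 and generic TSV are
taken as 1-based closed (TSV readers can request the BED shift).
Chromosome names are compared as exact strings — `chr3` and `3` are
different sequences — with an optional strip/add-`chr` normalization hook
at read time, default off.

## The interval tree

Each node stores an integer key and the list of intervals overlapping
that key; intervals with `end < key` go left, `start > key` right.
Closed-interval semantics put any interval touching the key in the
node's overlap list. Duplicated spans with distinct payloads are all
stored and all returned.

**Key choice.** The default key is `floor((min start + max end) / 2)`
over the intervals routed to the subtree. The choice of key convention
affects only tree shape, never query results; `build_interval_tree`
accepts an alternative rule, custom keys are clamped into the routed
union span (which guarantees both children are strictly smaller than the
parent's item set, hence termination), and a test asserts query
equivalence across three different conventions. For the same reason no
test ever asserts a specific key value — only overlap-list contents and
the node ordering invariants.

**Empty overlap lists** are permitted: if no routed interval overlaps
the computed key, the node still splits. This keeps the build rule total
with no special cases.

**Cost accounting.** Rather than timing anything, tree queries can carry
an `OpCounter` tallying nodes visited and overlap-predicate evaluations.
The efficiency claims in the tests are stated against these counters
(e.g. a point query on 10,000 random intervals visits < 5 % of n nodes;
a 1,000 × 1,000 join evaluates < 5 % of the n·m predicates of the
cross-product filter). These thresholds are loose structural bounds, not
tuned numbers; on uniform data the observed values are far below them.

## The join

The build side (forest side) is whichever input has fewer rows, ties
going to the left input; `build_side=` forces it for testing. The build
side must fit in memory — the same constraint a driver-collected
broadcast index implies. "Distributed" execution is modeled as a
partitioned-probe contract: the probe table is split into `partitions`
contiguous chunks, each chunk probes the same immutable forest, and
outputs concatenate in chunk order. Correctness therefore cannot depend
on the partition count, and a test sweeps partitions ∈ {1, 2, 3, 8, 17}.

Output rows are A's columns then B's columns in query order regardless
of build side (name collisions get table-name prefixes); row order is
deterministic — probe-row major, build-rowid minor, re-sorted to B-major
after orientation, chosen purely for testability since overlap joins
have no natural order. Semantics are inner-join: probe rows with no
partner vanish. A row id emitted by the lookup stage that does not
resolve in the indexed table raises immediately — it can only mean
engine corruption, never valid input.

## The query dialect

Deliberately tiny: `SELECT` (columns or `*`), `FROM` a table or
`t1 RANGEJOIN t2 ON GENOMEOVERLAP((c,s,e),(c,s,e))`, and `WHERE` over
comparisons, AND/OR/NOT, integer +/− arithmetic, and two built-in
predicates (`CONTAINS_AT(seq, offset, sub)` and `CIGAR_ALL_M(cigar)`)
that make the allele filter expressible in one statement. No GROUP BY,
aggregates, ORDER BY or subqueries — selection, projection and interval
join cover the workload this package exists for. The parser is a
hand-written tokenizer + recursive-descent parser (the grammar is ten
productions; error messages carry character positions).

The classic spelling — plain `JOIN … ON` with the explicit conjunction
`chrom = chrom AND s1 <= e2 AND s2 <= e1` — is recognized structurally
and routed to the same engine; any other plain-join predicate is
rejected with a pointer to RANGEJOIN, keeping the engine interval-only.

Comparisons with missing values evaluate false (no three-valued logic):
the simplest contract that is fully testable. Comparing a string with a
number is an error, not a coercion. The single planner rule is predicate
pushdown: a WHERE that references only one table's columns is applied
before the join; a test asserts enabling/disabling it never changes
results (true for inner joins by construction).

## The allele filter

`alt_supporting_reads` = range join (reads × variants) followed by two
row filters: the CIGAR must be all-M, and the read must carry the ALT
string at read offset `variant.pos − read.pos` (valid because an all-M
alignment maps read offsets to reference positions linearly; no
realignment around indels is attempted — reads with indel or clipped
alignments are excluded outright). Allele comparison is
case-insensitive; `N` in the read never matches; multi-base ALTs are
compared as substrings and an ALT running past the read end counts as
absent rather than raising. These three conventions are deliberate
implementation choices — reasonable, conservative, and pinned by tests.

## The simulator

`simulate_tables` emulates a desk-scale resequencing slice: a
three-chromosome genome (1.0/0.8/0.6 Mb), 100 bp uniform-start reads,
SNV-style variant sites (10 % with 2–3 base alternate alleles),
non-overlapping gene annotations. Defaults (2,000 reads, 200 variants,
overlap fraction 0.3, alt-carrier fraction 0.2) keep every test and
example in seconds on one CPU while leaving joins non-trivial.

Two constructions make planted truth *exact* rather than approximate:
variant sites sit on a grid spaced more than a read length apart, so a
read can cover at most one site; and background reads are rejected from
every site's footprint, so the planted (read, variant) pairs are
precisely the overlapping pairs. Ref-carrying reads get the reference
base at the site (the ALT's first base always differs from REF, so they
can never satisfy the allele check by accident). A tenth of background
reads carry an insertion CIGAR so the all-M gate filters something real.

What the generator does **not** emulate: sequencing error, base
qualities, indel alignments over variant sites, coverage bias, diploid
genotypes, or realistic variant density. Passing tests demonstrate the
interval/relational machinery is exact under these conditions; they say
nothing about variant-calling accuracy on real data.

Two independent join oracles guard the engine: a vectorized
cross-product overlap filter (the quadratic baseline itself) and a
separately-coded plane-sweep pair counter; a test checks they agree with
each other before either is trusted against the tree.

## Problem sizes

Randomized equivalence runs 200 instances with up to 2,000 rows per side
over a 100 kb coordinate range (interval length ≤ 100), the scale at
which the whole suite stays under a minute while still exercising
thousands of overlap pairs per instance. The efficiency bound uses
1,000 × 1,000 rows over 1 Mb.

## Known limitations

- The forest is rebuilt per join; there is no persistence or incremental
  update (out of scope: serialized indexes, tabix-style region seeks).
- Build side must fit in memory; no spill-to-disk strategy.
- Overlap only: no distance/nearest-neighbour or slop-windowed joins,
  and no strand-aware matching.
- The dialect has no aggregation; compose in Python for anything beyond
  select/project/join/filter.
- Partitioned execution is a correctness contract, not a performance
  feature: chunks are probed sequentially in-process.
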