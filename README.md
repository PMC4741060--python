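# gjoin — interval-forest range joins for genomic tables

Joining genomic tables on *interval overlap* — which reads cover which
variant sites, which variants fall inside which genes — is the workhorse
relational operation of sequencing analysis, and the naive way to do it is
a filter over the full cross product: for a billion reads against a
million variants that is 10^15 pair checks, which is not an option.
`gjoin` is a small library (plus a thin CLI) for doing these joins with a
**per-chromosome forest of centered interval trees**, so each probe costs
roughly a logarithmic tree walk instead of a scan of the whole other
table.

It is aimed at people who work with BED/GFF/VCF/SAM tables at desk scale
and want interval joins as a first-class, composable, *testable*
operation — including as a one-line SQL query.

## The model

All coordinates are **1-based and closed**; two intervals overlap iff
`max(starts) <= min(ends)`, and chromosomes never mix.

A **centered interval tree** stores n intervals in a binary tree. Each
node holds an integer *key* (the midpoint of the union span of the
intervals routed to its subtree) and the list of intervals overlapping
that key; intervals ending left of the key (`end < key`) go to the left
child, those starting right of it (`start > key`) to the right. Build is
O(n log n); a query walks only the root-to-leaf paths its span straddles.
An **interval forest** is a hash of chromosome name → tree.

A **range join** of tables A (smaller, "build side") and B runs in four
stages:

1. `index_table` — A1: assign dense row ids 0..n−1 to A in row order;
2. `extract_interval_keys` — A2: project each row to (interval, rowid);
3. `broadcast_forest` — build one forest over A2 and share it, read-only,
   with every execution partition;
4. `lookup_stage` + `materialize` — split B into contiguous partitions,
   probe each row against the forest (T1: B-record → A-rowid pairs), then
   resolve the row ids back to A records (T: one output row per
   overlapping pair).

The partitioned-probe contract means results are provably independent of
the partition count and of which side the forest is built from — both are
tested invariances.

On top of the join sit a tiny SQL dialect
(`SELECT … FROM A RANGEJOIN B ON GENOMEOVERLAP((c1,s1,e1),(c2,s2,e2))
[WHERE …]`) and a demonstration filter, `alt_supporting_reads`, which
finds reads that align with all-M CIGARs, overlap a variant site, and
carry its alternate allele at that position.

## A worked example

Table A holds two genes on chr3 (`gene1` at 100–1000, `gene2` at
4000–5000); table B holds three reads (`read1` chr3:150–250, `read2`
chr4:3000–3100, `read3` chr1:1000–1100). Running
`python examples/02_range_join.py`:

```
A2 interval keys : [('chr3', 100, 1000, 0), ('chr3', 4000, 5000, 1)]
T1 lookup pairs  : [(('read1', 'chr3', 150, 250), 0)]
join columns     : ['genes.id', 'genes.chrom', 'txStart', 'txEnd', 'function', 'reads.id', 'reads.chrom', 'readStart', 'readEnd']
join row         : ('gene1', 'chr3', 100, 1000, 'function1', 'read1', 'chr3', 150, 250)
overlap checks   : {'tree': 1, 'brute_force': 6, 'nodes_visited': 2}
```

Only `read1` overlaps a gene: the lookup stage emits a single pair whose
pointer (rowid 0) is the index of `gene1`, and materialization resolves
it into the one output row. The counters show the tree evaluated the
overlap predicate once where the cross-product filter would have done
2 × 3 = 6 evaluations; on 1,000 × 1,000-row uniform tables the tree does
under 5 % of the brute-force work (a tested property).

The same join as a query:

```python
from gjoin import Catalog, run, worked_example_fixtures

fx = worked_example_fixtures()
catalog = Catalog()
catalog.register("A", fx["genes"]); catalog.register("B", fx["reads"])
run("SELECT * FROM A RANGEJOIN B "
    "ON GENOMEOVERLAP((chrom, txStart, txEnd), (chrom, readStart, readEnd))",
    catalog).rows
# [('gene1', 'chr3', 100, 1000, 'function1', 'read1', 'chr3', 150, 250)]
```

Other examples: `examples/01_interval_tree.py` (tree build + search),
`examples/03_query_dialect.py` (dialect queries, including the classic
`JOIN … ON` overlap spelling), `examples/04_alt_supporting_reads.py`
(simulated study; the filter recovers exactly the 120 planted
alt-carrying reads out of 2,000).

## Command line

```bash
gjoin simulate --seed 3 --n-reads 1000 --outdir sim/        # SAM/VCF/GFF + truth
gjoin rangejoin --left sim/reads.sam --right sim/variants.vcf --stats --out join.tsv
gjoin query -q "SELECT qname, alt FROM R RANGEJOIN V \
    ON GENOMEOVERLAP((chrom,pos,end),(chrom,pos,end)) \
    WHERE CIGAR_ALL_M(cigar) AND CONTAINS_AT(seq, V.pos - R.pos, alt)" \
    --table R=sim/reads.sam --table V=sim/variants.vcf
gjoin altreads --reads sim/reads.sam --variants sim/variants.vcf --out alt.tsv
```

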