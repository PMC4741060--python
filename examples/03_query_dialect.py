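"""Run dialect queries: a range selection and a RANGEJOIN.

RANGEJOIN replaces JOIN, and GENOMEOVERLAP((c1,s1,e1),(c2,s2,e2)) names
each table's chromosome/start/end columns as the overlap condition.
"""

from gjoin import Catalog, run, worked_example_fixtures

fx = worked_example_fixtures()
catalog = Catalog()
catalog.register("A", fx["genes"])
catalog.register("B", fx["reads"])

selection = run(
    "SELECT id, readStart, readEnd FROM B "
    "WHERE chrom = 'chr3' AND readStart >= 100 AND readEnd <= 1000",
    catalog,
)
print("reads inside chr3:100-1000 :", selection.rows)

join = run(
    "SELECT * FROM A RANGEJOIN B "
    "ON GENOMEOVERLAP((chrom, txStart, txEnd), (chrom, readStart, readEnd))",
    catalog,
)
print("RANGEJOIN result           :", join.rows)

# The pre-extension spelling works too, when its ON clause is exactly the
# overlap conjunction; it is routed to the same interval-join engine:
classic = run(
    "SELECT B.id, A.id FROM A JOIN B "
    "ON chrom = chrom AND txStart <= readEnd AND readStart <= txEnd",
    catalog,
)
print("classic JOIN spelling      :", classic.rows)
# All three queries find the same fact: only read1 falls inside gene1.
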