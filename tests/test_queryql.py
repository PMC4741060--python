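"""Dialect grammar and executor: parsing, round trips, oracle equivalence."""

import numpy as np
import pytest

from conftest import random_table
from gjoin import queryql as q
from gjoin.queryql import Catalog, QueryError, RangeJoinClause, Scan, parse, to_sql
from gjoin.sim import brute_force_join


def catalog_for(fixtures):
    cat = Catalog()
    cat.register("A", fixtures["genes"])
    cat.register("B", fixtures["reads"])
    return cat


JOIN_QUERY = (
    "SELECT * FROM A RANGEJOIN B "
    "ON GENOMEOVERLAP((chrom, txStart, txEnd), (chrom, readStart, readEnd))"
)


class TestParse:
    def test_rangejoin_clause(self):
        ast = parse(
            "SELECT * FROM A RANGEJOIN B "
            "ON GENOMEOVERLAP((aChr,aStart,aEnd),(bChr,bStart,bEnd))"
        )
        assert isinstance(ast.source, RangeJoinClause)
        assert [c.name for c in ast.source.overlap.left] == ["aChr", "aStart", "aEnd"]
        assert [c.name for c in ast.source.overlap.right] == ["bChr", "bStart", "bEnd"]
        assert ast.select is None and ast.where is None

    def test_plain_scan(self):
        ast = parse("SELECT * FROM A")
        assert ast.source == Scan(table="A")

    def test_keywords_case_insensitive_identifiers_not(self):
        ast = parse("select x From tbl where x = 1")
        assert ast.source == Scan(table="tbl")
        assert ast.select[0].name == "x"

    def test_genomeoverlap_arity_errors(self):
        with pytest.raises(QueryError, match="exactly two"):
            parse("SELECT * FROM A RANGEJOIN B ON GENOMEOVERLAP((c,s,e),(c,s,e),(c,s,e))")
        with pytest.raises(QueryError, match="exactly \\(chrom, start, end\\)"):
            parse("SELECT * FROM A RANGEJOIN B ON GENOMEOVERLAP((c,s),(c,s,e))")

    def test_syntax_error_reports_position(self):
        with pytest.raises(QueryError, match="position"):
            parse("SELECT * FROM A WHERE x = = 1")
        with pytest.raises(QueryError, match="end of query"):
            parse("SELECT * FROM")

    def test_string_literal_escaping(self):
        ast = parse("SELECT * FROM A WHERE name = 'it''s'")
        assert ast.where.right.value == "it's"

    def test_plain_join_with_overlap_pattern_accepted(self):
        ast = parse(
            "SELECT * FROM A JOIN B ON "
            "aChr = bChr AND aStart <= bEnd AND bStart <= aEnd"
        )
        assert isinstance(ast.source, RangeJoinClause)

    def test_plain_join_with_other_predicate_rejected(self):
        with pytest.raises(QueryError, match="RANGEJOIN"):
            parse("SELECT * FROM A JOIN B ON aId = bId")

    def test_random_ast_round_trip(self):
        rng = np.random.default_rng(77)

        def rand_expr(depth):
            kind = int(rng.integers(0, 6 if depth < 3 else 3))
            col = q.ColumnRef(
                name=f"c{int(rng.integers(0, 5))}",
                table=None if rng.random() < 0.5 else f"t{int(rng.integers(0, 2))}",
            )
            lit = (q.Literal(int(rng.integers(0, 100))) if rng.random() < 0.6
                   else q.Literal(f"s{int(rng.integers(0, 9))}"))
            ops = ["=", "!=", "<", "<=", ">", ">="]
            if kind == 0:
                return q.BinOp(op=ops[int(rng.integers(0, 6))], left=col, right=lit)
            if kind == 1:
                arith = q.BinOp(op="-", left=col, right=q.Literal(3))
                return q.BinOp(op="<", left=arith, right=lit if isinstance(
                    lit.value, int) else q.Literal(7))
            if kind == 2:
                return q.FuncCall(name="CONTAINS_AT",
                                  args=(col, q.Literal(2), q.Literal("AC")))
            if kind == 3:
                return q.NotOp(operand=rand_expr(depth + 1))
            op = "AND" if rng.random() < 0.5 else "OR"
            return q.BoolOp(op=op, operands=(rand_expr(depth + 1),
                                             rand_expr(depth + 1)))

        for _ in range(100):
            select = None if rng.random() < 0.3 else tuple(
                q.ColumnRef(name=f"c{k}") for k in range(int(rng.integers(1, 4)))
            )
            if rng.random() < 0.5:
                source = Scan(table="T")
            else:
                triple = tuple(q.ColumnRef(name=n) for n in ("c", "s", "e"))
                source = RangeJoinClause(
                    left="T", right="U",
                    overlap=q.OverlapSpec(left=triple, right=triple),
                )
            ast = q.Query(
                select=select, source=source,
                where=None if rng.random() < 0.3 else rand_expr(0),
            )
            assert parse(to_sql(ast)) == ast


class TestExecute:
    def test_range_selection_on_fixture_reads(self, fixtures):
        cat = catalog_for(fixtures)
        t = q.run(
            "SELECT id FROM B WHERE chrom = 'chr3' "
            "AND readStart >= 100 AND readEnd <= 1000",
            cat,
        )
        assert t.rows == [("read1",)]

    def test_fixture_rangejoin_query(self, fixtures):
        t = q.run(JOIN_QUERY, catalog_for(fixtures))
        assert t.rows == [
            ("gene1", "chr3", 100, 1000, "function1", "read1", "chr3", 150, 250)
        ]

    def test_projection_order_and_qualification(self, fixtures):
        t = q.run(
            "SELECT B.id, A.id, function FROM A RANGEJOIN B "
            "ON GENOMEOVERLAP((chrom,txStart,txEnd),(chrom,readStart,readEnd))",
            catalog_for(fixtures),
        )
        assert t.schema.names() == ["B.id", "A.id", "function"]
        assert t.rows == [("read1", "gene1", "function1")]

    def test_ambiguous_column_rejected(self, fixtures):
        with pytest.raises(QueryError, match="ambiguous"):
            q.run(
                "SELECT id FROM A RANGEJOIN B "
                "ON GENOMEOVERLAP((chrom,txStart,txEnd),(chrom,readStart,readEnd))",
                catalog_for(fixtures),
            )

    def test_unknown_table_and_column(self, fixtures):
        cat = catalog_for(fixtures)
        with pytest.raises(QueryError, match="unknown table"):
            q.run("SELECT * FROM missing", cat)
        with pytest.raises(QueryError, match="unknown column"):
            q.run("SELECT * FROM A WHERE nope = 1", cat)

    def test_type_mismatch_in_comparison(self, fixtures):
        with pytest.raises(QueryError, match="type mismatch"):
            q.run("SELECT * FROM A WHERE txStart = 'x'", catalog_for(fixtures))

    def test_scan_equals_filter_plus_projection(self):
        rng = np.random.default_rng(19)
        t = random_table(rng, 400, name="t")
        cat = Catalog()
        cat.register("T", t)
        got = q.run("SELECT label FROM T WHERE chrom = 'chr2' AND start > 5000", cat)
        expected = [
            (row[3],) for row in t.rows if row[0] == "chr2" and row[1] > 5000
        ]
        assert got.rows == expected

    @pytest.mark.parametrize("seed", range(50))
    def test_join_where_equals_oracle_filter(self, seed):
        rng = np.random.default_rng(1000 + seed)
        a = random_table(rng, int(rng.integers(5, 60)), name="a")
        b = random_table(rng, int(rng.integers(5, 60)), name="b")
        cat = Catalog()
        cat.register("A", a)
        cat.register("B", b)
        cutoff = int(rng.integers(1, 10_000))
        got = q.run(
            "SELECT * FROM A RANGEJOIN B "
            "ON GENOMEOVERLAP((A.chrom,A.start,A.end),(B.chrom,B.start,B.end)) "
            f"WHERE A.start < {cutoff}",
            cat,
        )
        expected = sorted(
            tuple(a.rows[i]) + tuple(b.rows[j])
            for i, j in brute_force_join(a, b)
            if a.rows[i][1] < cutoff
        )
        assert sorted(got.rows) == expected

    def test_pushdown_invariance(self, fixtures):
        cat = catalog_for(fixtures)
        query = (
            "SELECT * FROM A RANGEJOIN B "
            "ON GENOMEOVERLAP((chrom,txStart,txEnd),(chrom,readStart,readEnd)) "
            "WHERE function = 'function1'"
        )
        with_pd = q.run(query, cat, pushdown=True)
        without_pd = q.run(query, cat, pushdown=False)
        assert with_pd.rows == without_pd.rows == [
            ("gene1", "chr3", 100, 1000, "function1", "read1", "chr3", 150, 250)
        ]

    def test_pushdown_invariance_randomized(self):
        rng = np.random.default_rng(55)
        a = random_table(rng, 80, name="a")
        b = random_table(rng, 80, name="b")
        cat = Catalog()
        cat.register("A", a)
        cat.register("B", b)
        query = (
            "SELECT * FROM A RANGEJOIN B "
            "ON GENOMEOVERLAP((A.chrom,A.start,A.end),(B.chrom,B.start,B.end)) "
            "WHERE B.end < 6000"
        )
        assert q.run(query, cat, pushdown=True).rows == q.run(
            query, cat, pushdown=False
        ).rows

    def test_missing_value_comparisons_are_false(self):
        from gjoin.tables import GenomicTable, Schema

        t = GenomicTable(
            name="t",
            schema=Schema(columns=[("x", "integer")]),
            rows=[(None,), (5,)],
        )
        cat = Catalog()
        cat.register("T", t)
        assert q.run("SELECT * FROM T WHERE x < 10", cat).rows == [(5,)]
        assert q.run("SELECT * FROM T WHERE x != 5", cat).rows == []

    def test_plain_join_routed_to_engine(self, fixtures):
        t = q.run(
            "SELECT * FROM A JOIN B ON "
            "chrom = chrom AND txStart <= readEnd AND readStart <= txEnd",
            catalog_for(fixtures),
        )
        assert len(t) == 1 and t.rows[0][0] == "gene1"
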