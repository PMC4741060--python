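"""A minimal SQL dialect for genomic tables.

The dialect covers exactly what interval-join workloads need: projection,
selection, and a range join spelled with two extra keywords::

    SELECT * FROM A RANGEJOIN B
        ON GENOMEOVERLAP((aChr, aStart, aEnd), (bChr, bStart, bEnd))
    WHERE ...

``RANGEJOIN`` replaces ``JOIN`` and ``GENOMEOVERLAP`` — whose two
arguments name each table's (chromosome, start, end) columns — is the only
admissible ``ON`` condition.  The classic spelling, a plain ``JOIN`` whose
``ON`` condition is the explicit conjunction of a chromosome equality and
the two start/end inequalities, is also accepted and routed to the same
interval-join engine; any other plain-``JOIN`` predicate is rejected.

Keywords are case-insensitive, identifiers case-sensitive.  String
literals use single quotes with ``''`` as the escape.  WHERE expressions
support comparisons (=, !=, <, <=, >, >=), AND/OR/NOT, integer +/-
arithmetic, and two built-in predicates used by allele filtering:

* ``CONTAINS_AT(seq, offset, sub)`` — true iff ``sub`` occurs in ``seq``
  at 0-based ``offset`` (case-insensitive; ``N`` in ``seq`` never
  matches; out-of-bounds offsets are false, not errors);
* ``CIGAR_ALL_M(cigar)`` — true iff every CIGAR operation is M.

Comparisons involving a missing value evaluate false (no three-valued
logic).  There is no GROUP BY, aggregation, ORDER BY or subquery.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

from .filters import cigar_is_all_match, sequence_contains_at
from .rangejoin import range_join
from .tables import GenomicTable, Schema

__all__ = [
    "Catalog",
    "QueryError",
    "parse",
    "to_sql",
    "execute",
    "Query",
    "Scan",
    "RangeJoinClause",
    "OverlapSpec",
]


class QueryError(ValueError):
    """Syntax or binding error in a dialect query."""


# ---------------------------------------------------------------------------
# AST


@dataclass(frozen=True)
class ColumnRef:
    name: str
    table: Optional[str] = None

    def sql(self) -> str:
        return f"{self.table}.{self.name}" if self.table else self.name


@dataclass(frozen=True)
class Literal:
    value: Union[int, float, str]

    def sql(self) -> str:
        if isinstance(self.value, str):
            return "'" + self.value.replace("'", "''") + "'"
        return str(self.value)


@dataclass(frozen=True)
class BinOp:
    """Arithmetic (+, -) or comparison (=, !=, <, <=, >, >=) operation."""

    op: str
    left: "Expr"
    right: "Expr"

    def sql(self) -> str:
        return f"({self.left.sql()} {self.op} {self.right.sql()})"


@dataclass(frozen=True)
class BoolOp:
    op: str  # AND | OR
    operands: Tuple["Expr", ...]

    def sql(self) -> str:
        return "(" + f" {self.op} ".join(e.sql() for e in self.operands) + ")"


@dataclass(frozen=True)
class NotOp:
    operand: "Expr"

    def sql(self) -> str:
        return f"(NOT {self.operand.sql()})"


@dataclass(frozen=True)
class FuncCall:
    name: str  # CONTAINS_AT | CIGAR_ALL_M
    args: Tuple["Expr", ...]

    def sql(self) -> str:
        return f"{self.name}(" + ", ".join(a.sql() for a in self.args) + ")"


Expr = Union[ColumnRef, Literal, BinOp, BoolOp, NotOp, FuncCall]


@dataclass(frozen=True)
class OverlapSpec:
    """The two (chrom, start, end) column triples of GENOMEOVERLAP."""

    left: Tuple[ColumnRef, ColumnRef, ColumnRef]
    right: Tuple[ColumnRef, ColumnRef, ColumnRef]


@dataclass(frozen=True)
class Scan:
    table: str


@dataclass(frozen=True)
class RangeJoinClause:
    left: str
    right: str
    overlap: OverlapSpec


@dataclass(frozen=True)
class Query:
    select: Optional[Tuple[ColumnRef, ...]]  # None means '*'
    source: Union[Scan, RangeJoinClause]
    where: Optional[Expr] = None


# ---------------------------------------------------------------------------
# Tokenizer

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<number>\d+(?:\.\d+)?)
  | (?P<string>'(?:[^']|'')*')
  | (?P<ident>[A-Za-z_][A-Za-z_0-9]*(?:\.[A-Za-z_][A-Za-z_0-9]*)?)
  | (?P<op><=|>=|!=|=|<|>|\(|\)|,|\*|\+|-)
    """,
    re.VERBOSE,
)

_KEYWORDS = {
    "SELECT", "FROM", "WHERE", "AND", "OR", "NOT", "ON",
    "JOIN", "RANGEJOIN", "GENOMEOVERLAP",
}
_FUNCTIONS = {"CONTAINS_AT", "CIGAR_ALL_M"}


@dataclass(frozen=True)
class _Token:
    kind: str  # keyword | ident | number | string | op | eof
    text: str
    pos: int


def _tokenize(query: str) -> List[_Token]:
    tokens: List[_Token] = []
    pos = 0
    while pos < len(query):
        m = _TOKEN_RE.match(query, pos)
        if m is None:
            raise QueryError(
                f"syntax error at position {pos}: unexpected character {query[pos]!r}"
            )
        pos = m.end()
        kind = m.lastgroup
        if kind == "ws":
            continue
        text = m.group()
        if kind == "ident" and text.upper() in _KEYWORDS:
            tokens.append(_Token("keyword", text.upper(), m.start()))
        else:
            tokens.append(_Token(kind, text, m.start()))
    tokens.append(_Token("eof", "", len(query)))
    return tokens


# ---------------------------------------------------------------------------
# Parser (recursive descent with token-index backtracking)


class _Parser:
    def __init__(self, query: str) -> None:
        self.query = query
        self.tokens = _tokenize(query)
        self.i = 0

    # -- token helpers ------------------------------------------------------

    def peek(self) -> _Token:
        return self.tokens[self.i]

    def advance(self) -> _Token:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def error(self, message: str) -> "QueryError":
        tok = self.peek()
        where = f"position {tok.pos}" if tok.kind != "eof" else "end of query"
        return QueryError(f"syntax error at {where}: {message}")

    def expect_keyword(self, word: str) -> None:
        tok = self.peek()
        if tok.kind != "keyword" or tok.text != word:
            raise self.error(f"expected {word}, found {tok.text or 'end of query'!r}")
        self.advance()

    def expect_op(self, op: str) -> None:
        tok = self.peek()
        if tok.kind != "op" or tok.text != op:
            raise self.error(f"expected {op!r}, found {tok.text or 'end of query'!r}")
        self.advance()

    def at_op(self, *ops: str) -> bool:
        tok = self.peek()
        return tok.kind == "op" and tok.text in ops

    def ident(self) -> str:
        tok = self.peek()
        if tok.kind != "ident":
            raise self.error(f"expected identifier, found {tok.text or 'end of query'!r}")
        self.advance()
        return tok.text

    def column_ref(self) -> ColumnRef:
        name = self.ident()
        if "." in name:
            table, col = name.split(".", 1)
            return ColumnRef(name=col, table=table)
        return ColumnRef(name=name)

    # -- grammar ------------------------------------------------------------

    def parse_query(self) -> Query:
        self.expect_keyword("SELECT")
        select = self.select_list()
        self.expect_keyword("FROM")
        source = self.from_clause()
        where = None
        tok = self.peek()
        if tok.kind == "keyword" and tok.text == "WHERE":
            self.advance()
            where = self.expr()
        if self.peek().kind != "eof":
            raise self.error(f"unexpected trailing input {self.peek().text!r}")
        return Query(select=select, source=source, where=where)

    def select_list(self) -> Optional[Tuple[ColumnRef, ...]]:
        if self.at_op("*"):
            self.advance()
            return None
        cols = [self.column_ref()]
        while self.at_op(","):
            self.advance()
            cols.append(self.column_ref())
        return tuple(cols)

    def from_clause(self) -> Union[Scan, RangeJoinClause]:
        left = self.ident()
        tok = self.peek()
        if tok.kind == "keyword" and tok.text == "RANGEJOIN":
            self.advance()
            right = self.ident()
            self.expect_keyword("ON")
            self.expect_keyword("GENOMEOVERLAP")
            overlap = self.genomeoverlap_args()
            return RangeJoinClause(left=left, right=right, overlap=overlap)
        if tok.kind == "keyword" and tok.text == "JOIN":
            self.advance()
            right = self.ident()
            self.expect_keyword("ON")
            predicate = self.expr()
            overlap = _overlap_from_predicate(predicate)
            if overlap is None:
                raise QueryError(
                    "plain JOIN is supported only when its ON condition is the "
                    "interval-overlap pattern (chrom equality AND start1 <= end2 "
                    "AND start2 <= end1); use RANGEJOIN ... ON GENOMEOVERLAP "
                    "for interval joins"
                )
            return RangeJoinClause(left=left, right=right, overlap=overlap)
        return Scan(table=left)

    def genomeoverlap_args(self) -> OverlapSpec:
        self.expect_op("(")
        first = self.triple()
        self.expect_op(",")
        second = self.triple()
        if self.at_op(","):
            raise QueryError(
                "GENOMEOVERLAP takes exactly two (chrom, start, end) triples"
            )
        self.expect_op(")")
        return OverlapSpec(left=first, right=second)

    def triple(self) -> Tuple[ColumnRef, ColumnRef, ColumnRef]:
        self.expect_op("(")
        cols = [self.column_ref()]
        while self.at_op(","):
            self.advance()
            cols.append(self.column_ref())
        self.expect_op(")")
        if len(cols) != 3:
            raise QueryError(
                f"GENOMEOVERLAP triple must name exactly (chrom, start, end) "
                f"columns, got {len(cols)}"
            )
        return (cols[0], cols[1], cols[2])

    def expr(self) -> Expr:
        return self.or_expr()

    def or_expr(self) -> Expr:
        operands = [self.and_expr()]
        while self.peek().kind == "keyword" and self.peek().text == "OR":
            self.advance()
            operands.append(self.and_expr())
        if len(operands) == 1:
            return operands[0]
        return BoolOp(op="OR", operands=tuple(operands))

    def and_expr(self) -> Expr:
        operands = [self.not_expr()]
        while self.peek().kind == "keyword" and self.peek().text == "AND":
            self.advance()
            operands.append(self.not_expr())
        if len(operands) == 1:
            return operands[0]
        return BoolOp(op="AND", operands=tuple(operands))

    def not_expr(self) -> Expr:
        if self.peek().kind == "keyword" and self.peek().text == "NOT":
            self.advance()
            return NotOp(operand=self.not_expr())
        # '(': may open a boolean group or an arithmetic sub-expression;
        # try the boolean reading first and backtrack if it is followed by
        # an operator that demands a value.
        if self.at_op("("):
            saved = self.i
            try:
                self.advance()
                inner = self.expr()
                self.expect_op(")")
                if not self.at_op("=", "!=", "<", "<=", ">", ">=", "+", "-"):
                    return inner
            except QueryError:
                pass
            self.i = saved
        return self.predicate()

    def predicate(self) -> Expr:
        tok = self.peek()
        if tok.kind == "ident" and tok.text.upper() in _FUNCTIONS:
            return self.func_call()
        left = self.additive()
        tok = self.peek()
        if tok.kind == "op" and tok.text in ("=", "!=", "<", "<=", ">", ">="):
            self.advance()
            right = self.additive()
            return BinOp(op=tok.text, left=left, right=right)
        raise self.error("expected a comparison operator")

    def func_call(self) -> FuncCall:
        name = self.advance().text.upper()
        self.expect_op("(")
        args = [self.additive()]
        while self.at_op(","):
            self.advance()
            args.append(self.additive())
        self.expect_op(")")
        arity = {"CONTAINS_AT": 3, "CIGAR_ALL_M": 1}[name]
        if len(args) != arity:
            raise QueryError(f"{name} takes {arity} argument(s), got {len(args)}")
        return FuncCall(name=name, args=tuple(args))

    def additive(self) -> Expr:
        left = self.primary()
        while self.at_op("+", "-"):
            op = self.advance().text
            left = BinOp(op=op, left=left, right=self.primary())
        return left

    def primary(self) -> Expr:
        tok = self.peek()
        if tok.kind == "number":
            self.advance()
            text = tok.text
            return Literal(float(text) if "." in text else int(text))
        if tok.kind == "string":
            self.advance()
            return Literal(tok.text[1:-1].replace("''", "'"))
        if tok.kind == "ident":
            if tok.text.upper() in _FUNCTIONS:
                return self.func_call()
            return self.column_ref()
        if self.at_op("("):
            self.advance()
            inner = self.additive()
            self.expect_op(")")
            return inner
        raise self.error(f"expected a value, found {tok.text or 'end of query'!r}")


def _overlap_from_predicate(expr: Expr) -> Optional[OverlapSpec]:
    """Recognize the classic overlap conjunction in a plain-JOIN ON clause.

    The pattern is one chromosome equality plus the two inequalities
    ``s1 <= e2 AND s2 <= e1`` (any conjunct order; ``>=`` spelled either
    way).  Returns None when the predicate is anything else.
    """
    conjuncts: List[Expr] = []

    def flatten(e: Expr) -> bool:
        if isinstance(e, BoolOp) and e.op == "AND":
            return all(flatten(op) for op in e.operands)
        conjuncts.append(e)
        return isinstance(e, BinOp)

    if not flatten(expr):
        return None
    eqs = []
    les = []  # normalized to (small, big): small <= big
    for c in conjuncts:
        if not isinstance(c, BinOp):
            return None
        if not (isinstance(c.left, ColumnRef) and isinstance(c.right, ColumnRef)):
            return None
        if c.op == "=":
            eqs.append((c.left, c.right))
        elif c.op == "<=":
            les.append((c.left, c.right))
        elif c.op == ">=":
            les.append((c.right, c.left))
        else:
            return None
    if len(eqs) != 1 or len(les) != 2:
        return None
    (chrom1, chrom2) = eqs[0]
    (s1, e2), (s2, e1) = les
    # the two inequalities must cross: start of one side vs end of the other
    first = (chrom1, s1, e1)
    second = (chrom2, s2, e2)
    return OverlapSpec(left=first, right=second)


def parse(query: str) -> Query:
    """Parse a dialect query string into its AST."""
    return _Parser(query).parse_query()


def to_sql(ast: Query) -> str:
    """Render an AST back to canonical query text (parse(to_sql(q)) == q)."""
    select = "*" if ast.select is None else ", ".join(c.sql() for c in ast.select)
    if isinstance(ast.source, Scan):
        source = ast.source.table
    else:
        ov = ast.source.overlap
        lt = ", ".join(c.sql() for c in ov.left)
        rt = ", ".join(c.sql() for c in ov.right)
        source = (
            f"{ast.source.left} RANGEJOIN {ast.source.right} "
            f"ON GENOMEOVERLAP(({lt}), ({rt}))"
        )
    text = f"SELECT {select} FROM {source}"
    if ast.where is not None:
        text += f" WHERE {ast.where.sql()}"
    return text


# ---------------------------------------------------------------------------
# Execution


@dataclass
class Catalog:
    """Name -> table registry the executor resolves FROM clauses against."""

    tables: Dict[str, GenomicTable] = field(default_factory=dict)

    def register(self, name: str, table: GenomicTable) -> None:
        if name in self.tables:
            raise QueryError(f"table {name!r} already registered")
        self.tables[name] = table

    def get(self, name: str) -> GenomicTable:
        try:
            return self.tables[name]
        except KeyError:
            raise QueryError(f"unknown table {name!r}") from None


@dataclass
class _Binding:
    """Column-resolution context: output column -> (owner table, bare name)."""

    out_names: List[str]
    owners: List[Tuple[str, str]]  # (table name, original column name)

    def resolve(self, ref: ColumnRef) -> int:
        matches = [
            i for i, (owner, orig) in enumerate(self.owners)
            if orig == ref.name and (ref.table is None or ref.table == owner)
        ]
        if not matches:
            raise QueryError(f"unknown column {ref.sql()!r}")
        if len(matches) > 1:
            raise QueryError(
                f"ambiguous column {ref.sql()!r}: qualify it with a table name"
            )
        return matches[0]


def _binding_for(table: GenomicTable, owners: List[Tuple[str, str]]) -> _Binding:
    return _Binding(out_names=table.schema.names(), owners=owners)


def _eval(expr: Expr, row: tuple, binding: _Binding):
    if isinstance(expr, Literal):
        return expr.value
    if isinstance(expr, ColumnRef):
        return row[binding.resolve(expr)]
    if isinstance(expr, NotOp):
        return not _eval(expr.operand, row, binding)
    if isinstance(expr, BoolOp):
        if expr.op == "AND":
            return all(_eval(e, row, binding) for e in expr.operands)
        return any(_eval(e, row, binding) for e in expr.operands)
    if isinstance(expr, FuncCall):
        args = [_eval(a, row, binding) for a in expr.args]
        if expr.name == "CIGAR_ALL_M":
            return args[0] is not None and cigar_is_all_match(args[0])
        if expr.name == "CONTAINS_AT":
            seq, offset, sub = args
            if seq is None or offset is None or sub is None:
                return False
            return sequence_contains_at(seq, int(offset), sub)
        raise QueryError(f"unknown function {expr.name}")  # pragma: no cover
    if isinstance(expr, BinOp):
        left = _eval(expr.left, row, binding)
        right = _eval(expr.right, row, binding)
        if expr.op in ("+", "-"):
            if not all(isinstance(v, (int, float)) for v in (left, right)):
                raise QueryError(
                    f"arithmetic {expr.op!r} needs numeric operands, "
                    f"got {left!r} and {right!r}"
                )
            return left + right if expr.op == "+" else left - right
        if left is None or right is None:
            return False
        numeric = (int, float)
        if isinstance(left, numeric) != isinstance(right, numeric):
            raise QueryError(
                f"type mismatch comparing {left!r} with {right!r}"
            )
        if expr.op == "=":
            return left == right
        if expr.op == "!=":
            return left != right
        if expr.op == "<":
            return left < right
        if expr.op == "<=":
            return left <= right
        if expr.op == ">":
            return left > right
        return left >= right
    raise QueryError(f"cannot evaluate {expr!r}")  # pragma: no cover


def _referenced_tables(expr: Expr, binding: _Binding) -> set:
    owners = set()

    def walk(e: Expr) -> None:
        if isinstance(e, ColumnRef):
            owners.add(binding.owners[binding.resolve(e)][0])
        elif isinstance(e, BinOp):
            walk(e.left)
            walk(e.right)
        elif isinstance(e, BoolOp):
            for op in e.operands:
                walk(op)
        elif isinstance(e, NotOp):
            walk(e.operand)
        elif isinstance(e, FuncCall):
            for a in e.args:
                walk(a)

    walk(expr)
    return owners


def _rekeyed(table: GenomicTable, name: str, overlap_triple) -> GenomicTable:
    """View of a registered table under its query alias and overlap columns."""
    from .tables import IntervalKey

    chrom, start, end = overlap_triple
    for ref in (chrom, start, end):
        if ref.table is not None and ref.table != name:
            raise QueryError(
                f"GENOMEOVERLAP column {ref.sql()!r} does not belong to table {name!r}"
            )
    schema = Schema(
        columns=list(table.schema.columns),
        interval_key=IntervalKey(chrom.name, start.name, end.name),
    )
    return GenomicTable(name=name, schema=schema, rows=table.rows)


def execute(
    ast: Query,
    catalog: Catalog,
    partitions: int = 1,
    pushdown: bool = True,
) -> GenomicTable:
    """Run a parsed query against registered tables.

    Scans apply WHERE then SELECT; range joins run the interval-join engine
    and apply WHERE afterwards, except that a WHERE referencing a single
    table's columns is pushed down before the join (an optimization that
    never changes inner-join results; disable with ``pushdown=False``).
    """
    if isinstance(ast.source, Scan):
        table = catalog.get(ast.source.table)
        binding = _Binding(
            out_names=table.schema.names(),
            owners=[(ast.source.table, n) for n in table.schema.names()],
        )
        rows = table.rows
        if ast.where is not None:
            rows = [r for r in rows if _eval(ast.where, r, binding)]
        out = GenomicTable(
            name="result",
            schema=Schema(list(table.schema.columns), table.schema.interval_key),
            rows=list(rows),
        )
        return _project(out, ast.select, binding)

    left_base = catalog.get(ast.source.left)
    right_base = catalog.get(ast.source.right)
    left_triple, right_triple = ast.source.overlap.left, ast.source.overlap.right
    try:
        left = _rekeyed(left_base, ast.source.left, left_triple)
        right = _rekeyed(right_base, ast.source.right, right_triple)
    except (QueryError, ValueError):
        # a plain-JOIN predicate may list the right table's columns first;
        # retry with the triples swapped before giving up
        left = _rekeyed(left_base, ast.source.left, right_triple)
        right = _rekeyed(right_base, ast.source.right, left_triple)

    owners = [(ast.source.left, n) for n in left.schema.names()] + [
        (ast.source.right, n) for n in right.schema.names()
    ]
    full_binding = _Binding(
        out_names=[n for _, n in owners], owners=owners
    )

    where = ast.where
    if where is not None and pushdown:
        refs = _referenced_tables(where, full_binding)  # also validates refs
        if len(refs) == 1:
            side_name = next(iter(refs))
            side = left if side_name == ast.source.left else right
            solo = _Binding(
                out_names=side.schema.names(),
                owners=[(side_name, n) for n in side.schema.names()],
            )
            side.rows = [r for r in side.rows if _eval(where, r, solo)]
            where = None

    joined = range_join(left, right, partitions=partitions)
    binding = _Binding(out_names=joined.schema.names(), owners=owners)
    if where is not None:
        joined.rows = [r for r in joined.rows if _eval(where, r, binding)]
    joined.name = "result"
    return _project(joined, ast.select, binding)


def _project(
    table: GenomicTable,
    select: Optional[Tuple[ColumnRef, ...]],
    binding: _Binding,
) -> GenomicTable:
    if select is None:
        return table
    idx = [binding.resolve(c) for c in select]
    cols = [(binding.out_names[i], table.schema.columns[i][1]) for i in idx]
    # projection may drop interval-key columns; keep the schema keyless
    return GenomicTable(
        name=table.name,
        schema=Schema(columns=cols),
        rows=[tuple(row[i] for i in idx) for row in table.rows],
    )


def run(
    query: str,
    catalog: Catalog,
    partitions: int = 1,
    pushdown: bool = True,
) -> GenomicTable:
    """Parse and execute in one call."""
    return execute(parse(query), catalog, partitions=partitions, pushdown=pushdown)
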