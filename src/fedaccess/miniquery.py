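"""Deliberately small query language executed inside a node.

Supported statements (keywords case-insensitive)::

    SELECT * FROM <table> [WHERE <col> <op> <literal> [AND ...]]
    SELECT COUNT(*) FROM <table> [WHERE ...]
    SELECT <col>, COUNT(*) FROM <table> [WHERE ...] GROUP BY <col>

with ``<op>`` one of ``= == != < <= > >=`` and literals either quoted
strings or numbers.  No joins, no expressions, no side effects: requests
arriving in richer SQL or R syntax simply fail to parse and the query
ends in the failed state, which is the intended behavior for anything
outside this grammar.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .datastore import LocalDatastore

__all__ = ["MiniQueryError", "ParseError", "UnknownColumn", "parse_query",
           "run_mini_query"]


class MiniQueryError(Exception):
    pass


class ParseError(MiniQueryError):
    pass


class UnknownColumn(MiniQueryError):
    pass


_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<string>'[^']*'|"[^"]*")
      | (?P<number>-?\d+(?:\.\d+)?)
      | (?P<op><=|>=|!=|==|=|<|>)
      | (?P<punct>[(),*])
      | (?P<word>[A-Za-z_][A-Za-z0-9_]*)
    )""",
    re.VERBOSE,
)


def _tokenize(body: str) -> list[tuple[str, str]]:
    tokens = []
    pos = 0
    body = body.strip().rstrip(";")
    while pos < len(body):
        m = _TOKEN_RE.match(body, pos)
        if m is None:
            raise ParseError(f"unexpected character at position {pos}: {body[pos]!r}")
        kind = m.lastgroup
        tokens.append((kind, m.group(kind)))
        pos = m.end()
    return tokens


@dataclass(frozen=True)
class Predicate:
    column: str
    op: str
    literal: object


@dataclass(frozen=True)
class MiniQuery:
    table: str
    predicates: tuple[Predicate, ...]
    group_by: Optional[str]  # column for grouped COUNT
    count_only: bool  # bare COUNT(*) without grouping


class _Parser:
    def __init__(self, tokens: list[tuple[str, str]]):
        self.tokens = tokens
        self.i = 0

    def peek(self) -> Optional[tuple[str, str]]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, str]:
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of query")
        self.i += 1
        return tok

    def expect_word(self, word: str) -> None:
        kind, val = self.next()
        if kind != "word" or val.upper() != word:
            raise ParseError(f"expected {word}, got {val!r}")

    def expect_punct(self, punct: str) -> None:
        kind, val = self.next()
        if kind != "punct" or val != punct:
            raise ParseError(f"expected {punct!r}, got {val!r}")


def parse_query(body: str) -> MiniQuery:
    p = _Parser(_tokenize(body))
    p.expect_word("SELECT")
    kind, val = p.next()
    group_col: Optional[str] = None
    count_only = False
    if kind == "punct" and val == "*":
        pass
    elif kind == "word" and val.upper() == "COUNT":
        p.expect_punct("(")
        p.expect_punct("*")
        p.expect_punct(")")
        count_only = True
    elif kind == "word":
        group_col = val
        p.expect_punct(",")
        p.expect_word("COUNT")
        p.expect_punct("(")
        p.expect_punct("*")
        p.expect_punct(")")
    else:
        raise ParseError(f"unexpected select item {val!r}")
    p.expect_word("FROM")
    kind, table = p.next()
    if kind != "word":
        raise ParseError(f"expected table name, got {table!r}")

    predicates: list[Predicate] = []
    tok = p.peek()
    if tok is not None and tok[0] == "word" and tok[1].upper() == "WHERE":
        p.next()
        while True:
            kind, col = p.next()
            if kind != "word":
                raise ParseError(f"expected column name, got {col!r}")
            kind, op = p.next()
            if kind != "op":
                raise ParseError(f"expected comparison operator, got {op!r}")
            kind, lit = p.next()
            if kind == "string":
                literal: object = lit[1:-1]
            elif kind == "number":
                literal = float(lit) if "." in lit else int(lit)
            else:
                raise ParseError(f"expected literal, got {lit!r}")
            predicates.append(Predicate(col, "==" if op == "=" else op, literal))
            tok = p.peek()
            if tok is not None and tok[0] == "word" and tok[1].upper() == "AND":
                p.next()
                continue
            break

    tok = p.peek()
    if tok is not None and tok[0] == "word" and tok[1].upper() == "GROUP":
        p.next()
        p.expect_word("BY")
        kind, col = p.next()
        if kind != "word":
            raise ParseError(f"expected column name after GROUP BY, got {col!r}")
        if group_col is not None and group_col != col:
            raise ParseError(
                f"selected column {group_col!r} differs from GROUP BY column {col!r}"
            )
        if count_only:
            count_only = False
        group_col = col
    elif group_col is not None:
        raise ParseError("grouped COUNT requires a GROUP BY clause")

    if p.peek() is not None:
        raise ParseError(f"trailing tokens starting at {p.peek()[1]!r}")
    return MiniQuery(
        table=table,
        predicates=tuple(predicates),
        group_by=group_col,
        count_only=count_only,
    )


_OPS = {
    "==": lambda s, v: s == v,
    "!=": lambda s, v: s != v,
    "<": lambda s, v: s < v,
    "<=": lambda s, v: s <= v,
    ">": lambda s, v: s > v,
    ">=": lambda s, v: s >= v,
}


def run_mini_query(
    syntax_language: str, syntax_body: str, datastore: LocalDatastore
) -> pd.DataFrame:
    """Execute a mini-language query against the datastore.

    The language tag is recorded on the manifest but does not change the
    grammar; only bodies conforming to the mini language execute.
    Grouped counts are sorted by group key; an empty WHERE clause returns
    the full table.
    """
    q = parse_query(syntax_body)
    if q.table not in datastore:
        raise UnknownColumn(f"unknown table {q.table!r}")
    df = datastore.get(q.table)
    mask = pd.Series(True, index=df.index)
    for pred in q.predicates:
        if pred.column not in df.columns:
            raise UnknownColumn(f"unknown column {pred.column!r}")
        mask &= _OPS[pred.op](df[pred.column], pred.literal)
    selected = df[mask]
    if q.group_by is not None:
        if q.group_by not in df.columns:
            raise UnknownColumn(f"unknown column {q.group_by!r}")
        counts = (
            selected.groupby(q.group_by, sort=True)
            .size()
            .rename("count")
            .reset_index()
        )
        return counts
    if q.count_only:
        return pd.DataFrame({"count": [int(mask.sum())]})
    return selected.reset_index(drop=True)
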