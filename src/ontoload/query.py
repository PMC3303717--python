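"""Ontological queries over the loaded schema.

A query is a tree: a term, optionally chained through ``memberOf`` /
``hasMember`` to a child node, with an annotation predicate on some node —
the textual form mirrors the tree view, e.g.::

    regulatory_region memberOf (gene hasMember (CDS hasAnnotation product=VP35))

Every term is expanded to its is_a descendants through the cvpath table,
so asking for ``gene`` also retrieves ``mitochondrial_gene`` features.
Chain edges follow ``feature_relationship`` rows of type part_of or
member_of, transitively (the loader stores only minimal containing
parents, so e.g. CDS reaches its gene through the mRNA).
"""
from __future__ import annotations

import re
import sqlite3
from dataclasses import dataclass
from typing import Optional

from .errors import QueryError
from .ontology import OntologySnapshot

MEMBER_OF, HAS_MEMBER = "memberOf", "hasMember"
_CHAIN_RELTYPES = ("part_of", "member_of")


@dataclass
class QueryNode:
    term: str  # accession or term name
    child: Optional[tuple[str, "QueryNode"]] = None  # (memberOf|hasMember, node)
    annotation: Optional[tuple[str, str]] = None  # (qualifier name, value)


@dataclass
class QueryResult:
    rows: list[tuple]  # (feature id, entry accession, type accession, start, end, strand)


_TOKEN_RE = re.compile(r"\(|\)|=|\"[^\"]*\"|[^\s()=]+")


def parse_query(text: str) -> QueryNode:
    """Parse the parenthesized tree notation into a QueryNode."""
    tokens = _TOKEN_RE.findall(text)
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        if pos >= len(tokens):
            raise QueryError(f"unexpected end of query: {text!r}")
        tok = tokens[pos]
        pos += 1
        return tok

    def unquote(tok: str) -> str:
        return tok[1:-1] if tok.startswith('"') and tok.endswith('"') else tok

    def parse_node() -> QueryNode:
        term = take()
        if term in ("(", ")", MEMBER_OF, HAS_MEMBER, "hasAnnotation"):
            raise QueryError(f"expected a term, got {term!r}")
        node = QueryNode(term=term)
        while peek() in (MEMBER_OF, HAS_MEMBER, "hasAnnotation", "hasAnnonation"):
            op = take()
            if op in (MEMBER_OF, HAS_MEMBER):
                if node.child is not None:
                    raise QueryError("a node may chain to at most one child")
                if peek() == "(":
                    take()
                    sub = parse_node()
                    if take() != ")":
                        raise QueryError(f"missing ')' in {text!r}")
                else:
                    sub = parse_node()
                node.child = (op, sub)
            else:  # hasAnnotation (normalized spelling)
                name = unquote(take())
                if peek() == "=":
                    take()
                value = unquote(take())
                node.annotation = (name, value)
        return node

    node = parse_node()
    if pos != len(tokens):
        raise QueryError(f"trailing tokens in query: {tokens[pos:]!r}")
    return node


_RC_CTE = (
    "WITH RECURSIVE rc(s, o) AS ("
    " SELECT subject_id, object_id FROM feature_relationship"
    " WHERE reltype IN ({rels})"
    " UNION"
    " SELECT rc.s, fr.object_id FROM rc JOIN feature_relationship fr"
    " ON fr.subject_id = rc.o AND fr.reltype IN ({rels})"
    ")"
).format(rels=", ".join(f"'{r}'" for r in _CHAIN_RELTYPES))


def compile_query(
    node: QueryNode, snapshot: OntologySnapshot, like: bool = False
) -> tuple[str, list]:
    """Compile a query tree to one SQL statement plus parameters."""
    params: list = []
    alias_n = 0

    def resolve(term: str) -> str:
        try:
            return snapshot.resolve_term(term)
        except Exception as exc:
            raise QueryError(str(exc)) from exc

    def conditions(n: QueryNode, alias: str) -> str:
        nonlocal alias_n
        conds = [
            f"{alias}.type_accession IN "
            "(SELECT subject FROM cvpath WHERE object = ? AND relationship = 'is_a')"
        ]
        params.append(resolve(n.term))
        if n.annotation is not None:
            name, value = n.annotation
            op = "LIKE" if like else "="
            conds.append(
                f"EXISTS (SELECT 1 FROM feature_annotation a WHERE a.feature_id = {alias}.id"
                f" AND a.name = ? AND a.value {op} ?)"
            )
            params.extend([name, f"%{value}%" if like else value])
        if n.child is not None:
            rel, sub = n.child
            alias_n += 1
            sub_alias = f"f{alias_n}"
            if rel == MEMBER_OF:
                edge = f"EXISTS (SELECT 1 FROM rc WHERE rc.s = {alias}.id AND rc.o = {sub_alias}.id)"
            elif rel == HAS_MEMBER:
                edge = f"EXISTS (SELECT 1 FROM rc WHERE rc.s = {sub_alias}.id AND rc.o = {alias}.id)"
            else:
                raise QueryError(f"unknown chain relationship {rel!r}")
            conds.append(
                f"EXISTS (SELECT 1 FROM sequence_feature {sub_alias}"
                f" WHERE {sub_alias}.entry_id = {alias}.entry_id AND {edge}"
                f" AND {conditions(sub, sub_alias)})"
            )
        return "(" + " AND ".join(conds) + ")"

    where = conditions(node, "f0")
    sql = (
        f"{_RC_CTE} "
        "SELECT f0.id, e.accession, f0.type_accession, f0.span_start, f0.span_end, f0.strand "
        "FROM sequence_feature f0 JOIN entry e ON f0.entry_id = e.id "
        f"WHERE {where} ORDER BY e.accession, f0.rank"
    )
    return sql, params


def execute_query(
    node: QueryNode,
    conn: sqlite3.Connection,
    snapshot: OntologySnapshot,
    like: bool = False,
) -> QueryResult:
    sql, params = compile_query(node, snapshot, like=like)
    return QueryResult(rows=conn.execute(sql, params).fetchall())
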