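"""Query algebra: triple patterns, basic graph patterns, operator tree.

A parsed query is a tree whose leaves are basic graph patterns (BGPs) and whose
internal nodes are Join (AND), Union, LeftJoin (OPTIONAL), Filter and Service.
Every triple pattern belongs to exactly one BGP and carries its BGP id and its
ordinal position inside that BGP, so downstream stages (source selection,
exclusive grouping) can address patterns stably.

OPTIONAL and UNION branches open fresh BGPs; FILTER does not interrupt a BGP.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Sequence, Set, Tuple, Union as TUnion

from .terms import IRI, BlankNode, Literal, RDF, Term, Variable, bound

__all__ = [
    "TriplePattern",
    "BasicGraphPattern",
    "BGPNode",
    "Join",
    "UnionNode",
    "LeftJoin",
    "FilterNode",
    "ServiceNode",
    "Expr",
    "TermExpr",
    "OrExpr",
    "AndExpr",
    "NotExpr",
    "Comparison",
    "Arithmetic",
    "FunctionCall",
    "ParsedQuery",
    "PatternKey",
    "pattern_variables",
    "expr_variables",
    "serialize_query",
    "serialize_node",
    "term_to_sparql",
]


@dataclass(frozen=True, slots=True)
class TriplePattern:
    """One subject–predicate–object template inside a BGP."""

    subject: Term
    predicate: Term
    object: Term
    ordinal: int = 0
    bgp_id: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.predicate, (Literal, type(None))):
            raise ValueError("a triple pattern's predicate must be an IRI or a variable")

    @property
    def key(self) -> "PatternKey":
        return (self.bgp_id, self.ordinal)

    def terms(self) -> Tuple[Term, Term, Term]:
        return (self.subject, self.predicate, self.object)

    def __str__(self) -> str:  # pragma: no cover
        return f"{self.subject.n3()} {self.predicate.n3()} {self.object.n3()}"


PatternKey = Tuple[int, int]  # (BGP id, pattern ordinal)


@dataclass(frozen=True, slots=True)
class BasicGraphPattern:
    id: int
    patterns: Tuple[TriplePattern, ...]

    def __iter__(self) -> Iterator[TriplePattern]:
        return iter(self.patterns)

    def __len__(self) -> int:
        return len(self.patterns)


# ---------------------------------------------------------------------------
# Operator tree


@dataclass
class BGPNode:
    bgp: BasicGraphPattern


@dataclass
class Join:
    parts: List["Node"]


@dataclass
class UnionNode:
    branches: List["Node"]


@dataclass
class LeftJoin:
    left: "Node"
    right: "Node"


@dataclass
class FilterNode:
    expr: "Expr"
    child: "Node"


@dataclass
class ServiceNode:
    endpoint: IRI
    child: "Node"
    silent: bool = False


Node = TUnion[BGPNode, Join, UnionNode, LeftJoin, FilterNode, ServiceNode]


# ---------------------------------------------------------------------------
# Filter expressions


class Expr:
    pass


@dataclass(frozen=True)
class TermExpr(Expr):
    term: Term


@dataclass(frozen=True)
class OrExpr(Expr):
    args: Tuple[Expr, ...]


@dataclass(frozen=True)
class AndExpr(Expr):
    args: Tuple[Expr, ...]


@dataclass(frozen=True)
class NotExpr(Expr):
    arg: Expr


@dataclass(frozen=True)
class Comparison(Expr):
    op: str  # = != < > <= >=
    left: Expr
    right: Expr


@dataclass(frozen=True)
class Arithmetic(Expr):
    op: str  # + - * /
    left: Expr
    right: Expr


@dataclass(frozen=True)
class FunctionCall(Expr):
    name: str  # upper-cased built-in name, e.g. REGEX
    args: Tuple[Expr, ...]


def expr_variables(expr: Expr) -> Set[str]:
    out: Set[str] = set()

    def walk(e: Expr) -> None:
        if isinstance(e, TermExpr):
            if isinstance(e.term, (Variable, BlankNode)):
                out.add(e.term.lexical)
        elif isinstance(e, (OrExpr, AndExpr, FunctionCall)):
            for a in e.args:
                walk(a)
        elif isinstance(e, NotExpr):
            walk(e.arg)
        elif isinstance(e, (Comparison, Arithmetic)):
            walk(e.left)
            walk(e.right)

    walk(expr)
    return out


def expr_functions(expr: Expr) -> Set[str]:
    out: Set[str] = set()

    def walk(e: Expr) -> None:
        if isinstance(e, FunctionCall):
            out.add(e.name)
            for a in e.args:
                walk(a)
        elif isinstance(e, (OrExpr, AndExpr)):
            for a in e.args:
                walk(a)
        elif isinstance(e, NotExpr):
            walk(e.arg)
        elif isinstance(e, (Comparison, Arithmetic)):
            walk(e.left)
            walk(e.right)

    walk(expr)
    return out


def pattern_variables(tp: TriplePattern) -> Set[str]:
    """Variable names of a pattern; blank nodes count as scoped variables."""
    return {t.lexical for t in tp.terms() if isinstance(t, (Variable, BlankNode))}


# ---------------------------------------------------------------------------
# Parsed query


@dataclass
class ParsedQuery:
    """A SPARQL SELECT or ASK query in algebra form."""

    form: str  # "SELECT" | "ASK"
    root: Node
    projection: Optional[List[str]]  # None means SELECT *
    distinct: bool = False
    limit: Optional[int] = None
    offset: Optional[int] = None
    order_by: List[Tuple[str, bool]] = field(default_factory=list)  # (var, ascending)
    prefixes: Dict[str, str] = field(default_factory=dict)
    original_text: str = ""

    @property
    def bgps(self) -> List[BasicGraphPattern]:
        out: List[BasicGraphPattern] = []
        for node in walk_nodes(self.root):
            if isinstance(node, BGPNode):
                out.append(node.bgp)
        return out

    def triple_patterns(self) -> List[TriplePattern]:
        """All triple patterns in syntactic order."""
        return [tp for bgp in self.bgps for tp in bgp]

    @property
    def tp_count(self) -> int:
        return len(self.triple_patterns())

    def filters(self) -> List[Expr]:
        return [n.expr for n in walk_nodes(self.root) if isinstance(n, FilterNode)]

    def clauses(self) -> Set[str]:
        """SPARQL clause names used by this query (the Table-style clause column)."""
        used: Set[str] = set()
        if self.distinct:
            used.add("DISTINCT")
        if self.limit is not None:
            used.add("LIMIT")
        if self.offset is not None:
            used.add("OFFSET")
        if self.order_by:
            used.add("ORDER BY")
        for node in walk_nodes(self.root):
            if isinstance(node, LeftJoin):
                used.add("OPTIONAL")
            elif isinstance(node, UnionNode):
                used.add("UNION")
            elif isinstance(node, FilterNode):
                used.add("FILTER")
                if "REGEX" in expr_functions(node.expr):
                    used.add("REGEX")
            elif isinstance(node, ServiceNode):
                used.add("SERVICE")
        return used

    def in_scope_variables(self) -> List[str]:
        seen: Dict[str, None] = {}
        for tp in self.triple_patterns():
            for t in tp.terms():
                if isinstance(t, Variable):
                    seen.setdefault(t.name)
        return list(seen)

    def effective_projection(self) -> List[str]:
        return self.projection if self.projection is not None else self.in_scope_variables()

    def to_sparql(self) -> str:
        return serialize_query(self)


def walk_nodes(node: Node) -> Iterator[Node]:
    """Pre-order traversal in syntactic order."""
    yield node
    if isinstance(node, Join):
        for p in node.parts:
            yield from walk_nodes(p)
    elif isinstance(node, UnionNode):
        for b in node.branches:
            yield from walk_nodes(b)
    elif isinstance(node, LeftJoin):
        yield from walk_nodes(node.left)
        yield from walk_nodes(node.right)
    elif isinstance(node, FilterNode):
        yield from walk_nodes(node.child)
    elif isinstance(node, ServiceNode):
        yield from walk_nodes(node.child)


# ---------------------------------------------------------------------------
# Serialization back to SPARQL text


def term_to_sparql(term: Term, prefixes: Optional[Dict[str, str]] = None) -> str:
    if isinstance(term, IRI) and prefixes:
        for pfx, base in sorted(prefixes.items(), key=lambda kv: -len(kv[1])):
            if term.value.startswith(base):
                local = term.value[len(base):]
                if local and all(c.isalnum() or c in "_-." for c in local) and not local.endswith("."):
                    return f"{pfx}:{local}"
    if isinstance(term, BlankNode):
        # blank nodes act as variables in query position; keep them as such
        return f"_:{term.label}"
    return term.n3()


def serialize_expr(expr: Expr, prefixes: Optional[Dict[str, str]] = None) -> str:
    if isinstance(expr, TermExpr):
        return term_to_sparql(expr.term, prefixes)
    if isinstance(expr, OrExpr):
        return "(" + " || ".join(serialize_expr(a, prefixes) for a in expr.args) + ")"
    if isinstance(expr, AndExpr):
        return "(" + " && ".join(serialize_expr(a, prefixes) for a in expr.args) + ")"
    if isinstance(expr, NotExpr):
        return f"(! {serialize_expr(expr.arg, prefixes)})"
    if isinstance(expr, (Comparison, Arithmetic)):
        return f"({serialize_expr(expr.left, prefixes)} {expr.op} {serialize_expr(expr.right, prefixes)})"
    if isinstance(expr, FunctionCall):
        return f"{expr.name}({', '.join(serialize_expr(a, prefixes) for a in expr.args)})"
    raise TypeError(f"unknown expression node {expr!r}")


def _serialize_pattern(tp: TriplePattern, prefixes: Optional[Dict[str, str]]) -> str:
    return " ".join(term_to_sparql(t, prefixes) for t in tp.terms())


def serialize_node(node: Node, prefixes: Optional[Dict[str, str]] = None, indent: int = 1) -> str:
    pad = "  " * indent

    def ser(n: Node) -> str:
        return serialize_node(n, prefixes, indent)

    if isinstance(node, BGPNode):
        return "\n".join(f"{pad}{_serialize_pattern(tp, prefixes)} ." for tp in node.bgp.patterns)
    if isinstance(node, Join):
        return "\n".join(ser(p) for p in node.parts if not _is_empty(p))
    if isinstance(node, UnionNode):
        blocks = [f"{pad}{{\n{serialize_node(b, prefixes, indent + 1)}\n{pad}}}" for b in node.branches]
        return f"\n{pad}UNION\n".join(blocks)
    if isinstance(node, LeftJoin):
        left = ser(node.left)
        right = serialize_node(node.right, prefixes, indent + 1)
        opt = f"{pad}OPTIONAL {{\n{right}\n{pad}}}"
        return f"{left}\n{opt}" if left.strip() else opt
    if isinstance(node, FilterNode):
        child = ser(node.child)
        flt = f"{pad}FILTER {serialize_expr(node.expr, prefixes)}"
        return f"{child}\n{flt}" if child.strip() else flt
    if isinstance(node, ServiceNode):
        silent = "SILENT " if node.silent else ""
        inner = serialize_node(node.child, prefixes, indent + 1)
        return f"{pad}SERVICE {silent}<{node.endpoint.value}> {{\n{inner}\n{pad}}}"
    raise TypeError(f"unknown algebra node {node!r}")


def _is_empty(node: Node) -> bool:
    return isinstance(node, BGPNode) and not node.bgp.patterns


def serialize_query(q: ParsedQuery) -> str:
    lines: List[str] = [f"PREFIX {p}: <{iri}>" for p, iri in q.prefixes.items()]
    if q.form == "ASK":
        header = "ASK"
    else:
        proj = "*" if q.projection is None else " ".join(f"?{v}" for v in q.projection)
        header = f"SELECT {'DISTINCT ' if q.distinct else ''}{proj} WHERE"
    body = serialize_node(q.root, q.prefixes or None, indent=1)
    lines.append(f"{header} {{\n{body}\n}}")
    if q.order_by:
        conds = " ".join(f"ASC(?{v})" if asc else f"DESC(?{v})" for v, asc in q.order_by)
        lines.append(f"ORDER BY {conds}")
    if q.limit is not None:
        lines.append(f"LIMIT {q.limit}")
    if q.offset is not None:
        lines.append(f"OFFSET {q.offset}")
    return "\n".join(lines) + "\n"
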