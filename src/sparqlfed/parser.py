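"""SPARQL parser for the SELECT/ASK subset the federation engine handles.

Grammar coverage: PREFIX/BASE prologue, SELECT (with DISTINCT, projection or
``*``) and ASK forms, basic graph patterns with ``;`` / ``,`` / ``a`` sugar,
FILTER constraints (logical connectives, comparisons, arithmetic, REGEX and the
common unary built-ins), OPTIONAL, UNION, SERVICE, and the solution modifiers
DISTINCT / ORDER BY / LIMIT / OFFSET.  Property paths, sub-selects, VALUES and
the update language are out of scope and rejected with a positioned error.

BGP identifiers and per-BGP pattern ordinals are assigned in syntactic order
after parsing, so the concatenation of all BGPs enumerates every triple pattern
exactly once, in the order written.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, List, Optional, Tuple

from .algebra import (
    AndExpr,
    Arithmetic,
    BGPNode,
    BasicGraphPattern,
    Comparison,
    Expr,
    FilterNode,
    FunctionCall,
    Join,
    LeftJoin,
    Node,
    NotExpr,
    OrExpr,
    ParsedQuery,
    ServiceNode,
    TermExpr,
    TriplePattern,
    UnionNode,
)
from .lexer import Token, TokenError, TokenStream, tokenize
from .terms import IRI, XSD, BlankNode, Literal, RDF, Term, Variable, is_absolute_iri

__all__ = ["parse_query", "QueryParseError"]

_BUILTINS = {
    "REGEX",
    "BOUND",
    "STR",
    "LANG",
    "DATATYPE",
    "CONTAINS",
    "STRSTARTS",
    "STRENDS",
    "ISIRI",
    "ISURI",
    "ISLITERAL",
    "ISBLANK",
    "LCASE",
    "UCASE",
    "STRLEN",
}

_UNSUPPORTED_FORMS = {"CONSTRUCT", "DESCRIBE", "INSERT", "DELETE", "VALUES"}


class QueryParseError(SyntaxError):
    """Raised on malformed query text; the message names line and column."""


def parse_query(text: str) -> ParsedQuery:
    """Parse SPARQL text into a :class:`ParsedQuery` algebra tree."""
    if not text or not text.strip():
        raise QueryParseError("empty query text (line 1, column 1)")
    try:
        parser = _Parser(text)
        q = parser.parse()
    except TokenError as exc:
        raise QueryParseError(str(exc)) from exc
    q.root = _number_patterns(q.root)
    return q


class _Parser:
    def __init__(self, text: str) -> None:
        self.text = text
        self.ts = TokenStream(tokenize(text))
        self.prefixes: Dict[str, str] = {}
        self.base = ""

    # -- entry --------------------------------------------------------------

    def parse(self) -> ParsedQuery:
        ts = self.ts
        self._prologue()
        if ts.at_keyword("SELECT"):
            q = self._select()
        elif ts.at_keyword("ASK"):
            q = self._ask()
        elif ts.at_keyword(*_UNSUPPORTED_FORMS):
            raise ts.error(f"unsupported query form {ts.current.value.upper()}")
        else:
            raise ts.error(f"expected SELECT or ASK, found {ts.current.value!r}")
        if ts.current.type != "eof":
            raise ts.error(f"trailing content {ts.current.value!r} after query")
        q.prefixes = dict(self.prefixes)
        q.original_text = self.text
        return q

    def _prologue(self) -> None:
        ts = self.ts
        while True:
            if ts.take_keyword("PREFIX"):
                tok = ts.current
                if tok.type != "pname" or tok.extra:
                    raise ts.error("expected a prefix label like 'ex:' after PREFIX")
                ts.advance()
                iri = ts.current
                if iri.type != "iri":
                    raise ts.error("expected an IRI after the prefix label")
                ts.advance()
                self.prefixes[tok.value] = self._resolve(iri.value)
            elif ts.take_keyword("BASE"):
                iri = ts.current
                if iri.type != "iri":
                    raise ts.error("expected an IRI after BASE")
                ts.advance()
                self.base = iri.value
            else:
                return

    def _resolve(self, iri: str) -> str:
        if is_absolute_iri(iri) or not self.base:
            return iri
        return self.base + iri

    # -- query forms --------------------------------------------------------

    def _select(self) -> ParsedQuery:
        ts = self.ts
        ts.expect_keyword("SELECT")
        distinct = bool(ts.take_keyword("DISTINCT"))
        ts.take_keyword("REDUCED")
        projection: Optional[List[str]]
        if ts.at_op("*"):
            ts.advance()
            projection = None
        else:
            projection = []
            while ts.current.type == "var":
                projection.append(ts.advance().value)
            if not projection:
                raise ts.error("expected '*' or at least one variable after SELECT")
        ts.take_keyword("WHERE")
        root = self._group()
        q = ParsedQuery(form="SELECT", root=root, projection=projection, distinct=distinct)
        self._modifiers(q)
        return q

    def _ask(self) -> ParsedQuery:
        ts = self.ts
        ts.expect_keyword("ASK")
        ts.take_keyword("WHERE")
        root = self._group()
        return ParsedQuery(form="ASK", root=root, projection=[])

    def _modifiers(self, q: ParsedQuery) -> None:
        ts = self.ts
        if ts.take_keyword("ORDER"):
            ts.expect_keyword("BY")
            while True:
                if ts.at_keyword("ASC", "DESC"):
                    asc = ts.advance().value.upper() == "ASC"
                    ts.expect_op("(")
                    var = ts.current
                    if var.type != "var":
                        raise ts.error("ORDER BY supports plain variables only")
                    ts.advance()
                    ts.expect_op(")")
                    q.order_by.append((var.value, asc))
                elif ts.current.type == "var":
                    q.order_by.append((ts.advance().value, True))
                else:
                    break
            if not q.order_by:
                raise ts.error("expected an ordering condition after ORDER BY")
        if ts.take_keyword("LIMIT"):
            q.limit = self._integer("LIMIT")
        if ts.take_keyword("OFFSET"):
            q.offset = self._integer("OFFSET")
        if ts.take_keyword("LIMIT") and q.limit is None:  # LIMIT after OFFSET
            q.limit = self._integer("LIMIT")

    def _integer(self, clause: str) -> int:
        ts = self.ts
        tok = ts.current
        if tok.type != "number" or not tok.value.lstrip("+-").isdigit():
            raise ts.error(f"expected an integer after {clause}")
        ts.advance()
        return int(tok.value)

    # -- group graph patterns ----------------------------------------------

    def _group(self) -> Node:
        ts = self.ts
        ts.expect_op("{")
        elements: List[Node] = []
        filters: List[Expr] = []
        pending: List[TriplePattern] = []

        def flush() -> None:
            if pending:
                elements.append(BGPNode(BasicGraphPattern(-1, tuple(pending))))
                pending.clear()

        while not ts.at_op("}"):
            if ts.current.type == "eof":
                raise ts.error("unterminated group: missing '}'")
            if ts.at_keyword("FILTER"):
                ts.advance()
                filters.append(self._constraint())
            elif ts.at_keyword("OPTIONAL"):
                ts.advance()
                right = self._group()
                flush()
                left: Node = Join(elements) if len(elements) != 1 else elements[0]
                if not elements:
                    left = BGPNode(BasicGraphPattern(-1, ()))
                elements = [LeftJoin(left, right)]
            elif ts.at_keyword("SERVICE"):
                ts.advance()
                silent = bool(ts.take_keyword("SILENT"))
                endpoint = self._term()
                if not isinstance(endpoint, IRI):
                    raise ts.error("SERVICE endpoint must be an IRI in this engine")
                child = self._group()
                flush()
                elements.append(ServiceNode(endpoint, child, silent))
            elif ts.at_op("{"):
                first = self._group()
                branches = [first]
                while ts.take_keyword("UNION"):
                    branches.append(self._group())
                flush()
                elements.append(UnionNode(branches) if len(branches) > 1 else first)
            elif ts.at_keyword("GRAPH", "MINUS", "BIND", "VALUES"):
                raise ts.error(f"unsupported clause {ts.current.value.upper()}")
            else:
                pending.extend(self._triples_block())
            while ts.at_op("."):
                ts.advance()
        ts.expect_op("}")
        flush()
        if not elements:
            node: Node = BGPNode(BasicGraphPattern(-1, ()))
        elif len(elements) == 1:
            node = elements[0]
        else:
            node = Join(elements)
        for f in filters:
            node = FilterNode(f, node)
        return node

    def _triples_block(self) -> List[TriplePattern]:
        ts = self.ts
        out: List[TriplePattern] = []
        subject = self._term()
        while True:
            predicate = self._verb()
            while True:
                obj = self._term()
                try:
                    out.append(TriplePattern(subject, predicate, obj))
                except ValueError as exc:
                    raise ts.error(str(exc)) from exc
                if ts.at_op(","):
                    ts.advance()
                    continue
                break
            if ts.at_op(";"):
                ts.advance()
                if ts.at_op(".", ";", "}") or ts.at_keyword("FILTER", "OPTIONAL", "UNION", "SERVICE"):
                    continue
                if ts.current.type == "eof":
                    break
                continue
            break
        return out

    def _verb(self) -> Term:
        ts = self.ts
        if ts.current.type == "ident" and ts.current.value == "a":
            ts.advance()
            return RDF.type
        t = self._term()
        if isinstance(t, (Literal, BlankNode)):
            raise ts.error("predicate must be an IRI or a variable")
        return t

    def _term(self) -> Term:
        ts = self.ts
        tok = ts.current
        if tok.type == "iri":
            ts.advance()
            return IRI(self._resolve(tok.value))
        if tok.type == "pname":
            ts.advance()
            if tok.value not in self.prefixes:
                raise TokenError(f"undeclared prefix {tok.value!r}", tok.line, tok.col)
            return IRI(self.prefixes[tok.value] + (tok.extra or ""))
        if tok.type == "var":
            ts.advance()
            return Variable(tok.value)
        if tok.type == "bnode":
            ts.advance()
            return BlankNode(tok.value)
        if tok.type == "string":
            ts.advance()
            if ts.current.type == "langtag":
                return Literal(tok.value, language=ts.advance().value)
            if ts.at_op("^^"):
                ts.advance()
                dt = self._term()
                if not isinstance(dt, IRI):
                    raise ts.error("datatype must be an IRI")
                return Literal(tok.value, datatype=dt)
            return Literal(tok.value)
        if tok.type == "number":
            ts.advance()
            if any(c in tok.value for c in ".eE"):
                dt = XSD.double if ("e" in tok.value or "E" in tok.value) else XSD.decimal
            else:
                dt = XSD.integer
            return Literal(tok.value, datatype=dt)
        if tok.type == "ident" and tok.value in ("true", "false"):
            ts.advance()
            return Literal(tok.value, datatype=XSD.boolean)
        if tok.type == "op" and tok.value == "[":
            ts.advance()
            if not ts.at_op("]"):
                raise ts.error("anonymous blank-node property lists are not supported")
            ts.advance()
            return BlankNode(f"anon{tok.line}_{tok.col}")
        raise ts.error(f"unexpected token {tok.value!r} where a term was expected")

    # -- filter constraints -------------------------------------------------

    def _constraint(self) -> Expr:
        ts = self.ts
        if ts.at_op("("):
            return self._bracketted()
        if ts.current.type == "ident" and ts.current.value.upper() in _BUILTINS:
            return self._function_call()
        raise ts.error("expected '(' or a built-in call after FILTER")

    def _bracketted(self) -> Expr:
        ts = self.ts
        ts.expect_op("(")
        e = self._expression()
        ts.expect_op(")")
        return e

    def _expression(self) -> Expr:
        return self._or_expr()

    def _or_expr(self) -> Expr:
        args = [self._and_expr()]
        while self.ts.at_op("||"):
            self.ts.advance()
            args.append(self._and_expr())
        return args[0] if len(args) == 1 else OrExpr(tuple(args))

    def _and_expr(self) -> Expr:
        args = [self._value_logical()]
        while self.ts.at_op("&&"):
            self.ts.advance()
            args.append(self._value_logical())
        return args[0] if len(args) == 1 else AndExpr(tuple(args))

    def _value_logical(self) -> Expr:
        ts = self.ts
        left = self._additive()
        if ts.at_op("=", "!=", "<", ">", "<=", ">="):
            op = ts.advance().value
            right = self._additive()
            return Comparison(op, left, right)
        return left

    def _additive(self) -> Expr:
        ts = self.ts
        left = self._multiplicative()
        while ts.at_op("+", "-"):
            op = ts.advance().value
            left = Arithmetic(op, left, self._multiplicative())
        return left

    def _multiplicative(self) -> Expr:
        ts = self.ts
        left = self._unary()
        while ts.at_op("*", "/"):
            op = ts.advance().value
            left = Arithmetic(op, left, self._unary())
        return left

    def _unary(self) -> Expr:
        ts = self.ts
        if ts.at_op("!"):
            ts.advance()
            return NotExpr(self._unary())
        if ts.at_op("-"):
            ts.advance()
            inner = self._unary()
            return Arithmetic("-", TermExpr(Literal("0", datatype=XSD.integer)), inner)
        if ts.at_op("+"):
            ts.advance()
            return self._unary()
        return self._primary()

    def _primary(self) -> Expr:
        ts = self.ts
        tok = ts.current
        if ts.at_op("("):
            return self._bracketted()
        if tok.type == "ident" and tok.value.upper() in _BUILTINS:
            return self._function_call()
        if tok.type == "ident" and tok.value not in ("true", "false"):
            raise ts.error(f"unknown function or keyword {tok.value!r} in expression")
        return TermExpr(self._term())

    def _function_call(self) -> Expr:
        ts = self.ts
        name = ts.advance().value.upper()
        if name == "ISURI":
            name = "ISIRI"
        ts.expect_op("(")
        args: List[Expr] = []
        if not ts.at_op(")"):
            args.append(self._expression())
            while ts.at_op(","):
                ts.advance()
                args.append(self._expression())
        ts.expect_op(")")
        return FunctionCall(name, tuple(args))


# ---------------------------------------------------------------------------
# Pattern numbering


def _number_patterns(root: Node) -> Node:
    """Assign BGP ids and in-BGP ordinals in syntactic order, rebuilding the tree."""
    counter = {"bgp": 0}

    def rebuild(node: Node) -> Node:
        if isinstance(node, BGPNode):
            bid = counter["bgp"]
            counter["bgp"] += 1
            patterns = tuple(
                replace(tp, ordinal=i, bgp_id=bid) for i, tp in enumerate(node.bgp.patterns)
            )
            return BGPNode(BasicGraphPattern(bid, patterns))
        if isinstance(node, Join):
            return Join([rebuild(p) for p in node.parts])
        if isinstance(node, UnionNode):
            return UnionNode([rebuild(b) for b in node.branches])
        if isinstance(node, LeftJoin):
            left = rebuild(node.left)
            return LeftJoin(left, rebuild(node.right))
        if isinstance(node, FilterNode):
            return FilterNode(node.expr, rebuild(node.child))
        if isinstance(node, ServiceNode):
            return ServiceNode(node.endpoint, rebuild(node.child), node.silent)
        raise TypeError(f"unknown node {node!r}")

    return rebuild(root)
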