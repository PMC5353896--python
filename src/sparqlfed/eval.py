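"""SPARQL evaluation over in-memory graphs, with pluggable SERVICE dispatch.

Bag (multiset) semantics throughout: BGPs extend partial solutions pattern by
pattern, Join merges compatible solutions, OPTIONAL is a left join, UNION
concatenates, FILTER keeps solutions whose constraint evaluates to true
(evaluation errors discard the solution, per the SPARQL error convention).
SERVICE blocks are delegated to a handler supplied by the caller — the
federation runtime wraps that handler with provenance instrumentation, while
plain local evaluation needs no handler at all.

Blank nodes in query position act as scoped variables; their bindings are
internal and never projected.
"""

from __future__ import annotations

import re
from collections import Counter
from typing import Callable, Dict, FrozenSet, Iterable, List, Optional, Tuple

from .algebra import (
    AndExpr,
    Arithmetic,
    BGPNode,
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
from .graph import Graph
from .terms import IRI, XSD, BlankNode, Literal, Term, Variable

__all__ = [
    "Solution",
    "evaluate_query",
    "evaluate_node",
    "evaluate_ask",
    "solution_multiset",
    "EvaluationError",
    "ServiceHandler",
]

Solution = Dict[str, Term]
ServiceHandler = Callable[[ServiceNode], List[Solution]]

_BNODE_PREFIX = "_:"  # internal solution keys for blank-node "variables"


class EvaluationError(RuntimeError):
    """Raised when a query needs a capability the context does not provide."""


class _FilterError(Exception):
    """SPARQL expression evaluation error (type error, unbound variable)."""


# ---------------------------------------------------------------------------
# Pattern matching


def _var_key(term: Term) -> Optional[str]:
    if isinstance(term, Variable):
        return term.name
    if isinstance(term, BlankNode):
        return _BNODE_PREFIX + term.label
    return None


def _match_bgp(patterns: Iterable[TriplePattern], graph: Graph, seed: Solution) -> List[Solution]:
    solutions: List[Solution] = [dict(seed)]
    for tp in patterns:
        next_solutions: List[Solution] = []
        for sol in solutions:
            template = []
            keys = []
            for term in tp.terms():
                k = _var_key(term)
                if k is None:
                    template.append(term)
                    keys.append(None)
                else:
                    template.append(sol.get(k))
                    keys.append(k)
            for triple in graph.match(*template):
                new = dict(sol)
                ok = True
                for k, value in zip(keys, triple):
                    if k is None:
                        continue
                    if k in new and new[k] != value:
                        ok = False
                        break
                    new[k] = value
                if ok:
                    next_solutions.append(new)
        solutions = next_solutions
        if not solutions:
            break
    return solutions


def _compatible(a: Solution, b: Solution) -> bool:
    return all(a[k] == b[k] for k in a.keys() & b.keys())


def _merge(a: Solution, b: Solution) -> Solution:
    out = dict(a)
    out.update(b)
    return out


# ---------------------------------------------------------------------------
# Node evaluation


def evaluate_node(
    node: Node,
    graph: Optional[Graph] = None,
    service_handler: Optional[ServiceHandler] = None,
) -> List[Solution]:
    if isinstance(node, BGPNode):
        if not node.bgp.patterns:
            return [{}]
        if graph is None:
            raise EvaluationError("query contains a bare BGP but no local graph was given")
        return _match_bgp(node.bgp.patterns, graph, {})
    if isinstance(node, Join):
        solutions: List[Solution] = [{}]
        for part in node.parts:
            part_solutions = evaluate_node(part, graph, service_handler)
            solutions = [
                _merge(a, b) for a in solutions for b in part_solutions if _compatible(a, b)
            ]
            if not solutions:
                return []
        return solutions
    if isinstance(node, UnionNode):
        out: List[Solution] = []
        for branch in node.branches:
            out.extend(evaluate_node(branch, graph, service_handler))
        return out
    if isinstance(node, LeftJoin):
        left = evaluate_node(node.left, graph, service_handler)
        right = evaluate_node(node.right, graph, service_handler)
        out = []
        for l in left:
            extensions = [_merge(l, r) for r in right if _compatible(l, r)]
            out.extend(extensions if extensions else [l])
        return out
    if isinstance(node, FilterNode):
        child = evaluate_node(node.child, graph, service_handler)
        return [sol for sol in child if _filter_passes(node.expr, sol)]
    if isinstance(node, ServiceNode):
        if service_handler is None:
            raise EvaluationError(
                f"SERVICE <{node.endpoint.value}> requires an endpoint registry"
            )
        return service_handler(node)
    raise TypeError(f"unknown algebra node {node!r}")


def evaluate_query(
    q: ParsedQuery,
    graph: Optional[Graph] = None,
    service_handler: Optional[ServiceHandler] = None,
) -> List[Solution]:
    """Evaluate a SELECT query; returns bindings as a list of dicts."""
    solutions = evaluate_node(q.root, graph, service_handler)
    projection = q.effective_projection()
    projected = [
        {v: sol[v] for v in projection if v in sol and not v.startswith(_BNODE_PREFIX)}
        for sol in solutions
    ]
    if q.distinct:
        seen = set()
        unique: List[Solution] = []
        for sol in projected:
            key = frozenset(sol.items())
            if key not in seen:
                seen.add(key)
                unique.append(sol)
        projected = unique
    if q.order_by:
        for var, asc in reversed(q.order_by):
            projected.sort(key=lambda s, v=var: _order_key(s.get(v)), reverse=not asc)
    if q.offset:
        projected = projected[q.offset:]
    if q.limit is not None:
        projected = projected[: q.limit]
    return projected


def evaluate_ask(
    q: ParsedQuery,
    graph: Optional[Graph] = None,
    service_handler: Optional[ServiceHandler] = None,
) -> bool:
    return bool(evaluate_node(q.root, graph, service_handler))


def _order_key(term: Optional[Term]) -> Tuple:
    if term is None:
        return (0, "", "")
    if isinstance(term, BlankNode):
        return (1, term.label, "")
    if isinstance(term, IRI):
        return (2, term.value, "")
    value = term.value
    if isinstance(value, bool):
        return (3, "", str(value))
    if isinstance(value, (int, float)):
        return (3, float(value), "")
    return (4, term.lexical, term.language or "")


def solution_multiset(solutions: Iterable[Solution]) -> Counter:
    """Canonical multiset of solutions, for order-insensitive comparison."""
    return Counter(frozenset(sol.items()) for sol in solutions)


# ---------------------------------------------------------------------------
# Filter expressions


def _filter_passes(expr: Expr, sol: Solution) -> bool:
    try:
        return _ebv(_eval_expr(expr, sol))
    except _FilterError:
        return False


def _ebv(value) -> bool:
    """Effective boolean value."""
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)):
        return value != 0
    if isinstance(value, str):
        return len(value) > 0
    raise _FilterError(f"no effective boolean value for {value!r}")


def _eval_expr(expr: Expr, sol: Solution):
    if isinstance(expr, TermExpr):
        term = expr.term
        if isinstance(term, (Variable, BlankNode)):
            key = term.name if isinstance(term, Variable) else _BNODE_PREFIX + term.label
            if key not in sol:
                raise _FilterError(f"unbound variable ?{key}")
            value = sol[key]
            return value.value if isinstance(value, Literal) else value
        if isinstance(term, Literal):
            return term.value
        return term  # IRI
    if isinstance(expr, OrExpr):
        error = False
        for arg in expr.args:
            try:
                if _ebv(_eval_expr(arg, sol)):
                    return True
            except _FilterError:
                error = True
        if error:
            raise _FilterError("OR over errors")
        return False
    if isinstance(expr, AndExpr):
        error = False
        for arg in expr.args:
            try:
                if not _ebv(_eval_expr(arg, sol)):
                    return False
            except _FilterError:
                error = True
        if error:
            raise _FilterError("AND over errors")
        return True
    if isinstance(expr, NotExpr):
        return not _ebv(_eval_expr(expr.arg, sol))
    if isinstance(expr, Comparison):
        return _compare(expr.op, _eval_expr(expr.left, sol), _eval_expr(expr.right, sol))
    if isinstance(expr, Arithmetic):
        left, right = _numeric(_eval_expr(expr.left, sol)), _numeric(_eval_expr(expr.right, sol))
        if expr.op == "+":
            return left + right
        if expr.op == "-":
            return left - right
        if expr.op == "*":
            return left * right
        if right == 0:
            raise _FilterError("division by zero")
        return left / right
    if isinstance(expr, FunctionCall):
        return _call(expr, sol)
    raise _FilterError(f"unsupported expression {expr!r}")


def _numeric(value) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise _FilterError(f"not a number: {value!r}")
    return value


def _compare(op: str, left, right) -> bool:
    if op in ("=", "!="):
        equal = _rdf_equal(left, right)
        return equal if op == "=" else not equal
    # ordering comparisons require two numbers or two strings
    if isinstance(left, (int, float)) and isinstance(right, (int, float)) and not (
        isinstance(left, bool) or isinstance(right, bool)
    ):
        pass
    elif isinstance(left, str) and isinstance(right, str):
        pass
    else:
        raise _FilterError(f"cannot order {left!r} and {right!r}")
    if op == "<":
        return left < right
    if op == ">":
        return left > right
    if op == "<=":
        return left <= right
    return left >= right


def _rdf_equal(left, right) -> bool:
    if isinstance(left, IRI) or isinstance(right, IRI):
        return isinstance(left, IRI) and isinstance(right, IRI) and left == right
    if isinstance(left, BlankNode) or isinstance(right, BlankNode):
        return left == right
    if isinstance(left, (int, float)) and isinstance(right, (int, float)) and not (
        isinstance(left, bool) or isinstance(right, bool)
    ):
        return left == right
    return left == right


def _string_of(value) -> str:
    if isinstance(value, IRI):
        return value.value
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return value
    raise _FilterError(f"no string form for {value!r}")


def _call(expr: FunctionCall, sol: Solution):
    name, args = expr.name, expr.args

    def arg(i: int):
        return _eval_expr(args[i], sol)

    if name == "BOUND":
        inner = args[0]
        if not isinstance(inner, TermExpr) or not isinstance(inner.term, (Variable, BlankNode)):
            raise _FilterError("BOUND expects a variable")
        key = (
            inner.term.name
            if isinstance(inner.term, Variable)
            else _BNODE_PREFIX + inner.term.label
        )
        return key in sol
    if name == "REGEX":
        text = _string_of(arg(0))
        pattern = _string_of(arg(1))
        flags = _string_of(arg(2)) if len(args) > 2 else ""
        re_flags = re.IGNORECASE if "i" in flags else 0
        try:
            return re.search(pattern, text, re_flags) is not None
        except re.error as exc:
            raise _FilterError(f"bad regex: {exc}") from exc
    if name == "STR":
        value = arg(0)
        if isinstance(value, Literal):  # pragma: no cover - literals arrive as python values
            return value.lexical
        return _string_of(value)
    if name == "LANG":
        inner = args[0]
        if isinstance(inner, TermExpr) and isinstance(inner.term, (Variable, BlankNode)):
            key = (
                inner.term.name
                if isinstance(inner.term, Variable)
                else _BNODE_PREFIX + inner.term.label
            )
            term = sol.get(key)
            if isinstance(term, Literal):
                return term.language or ""
        raise _FilterError("LANG expects a literal-valued variable")
    if name == "DATATYPE":
        inner = args[0]
        if isinstance(inner, TermExpr) and isinstance(inner.term, (Variable, BlankNode)):
            key = (
                inner.term.name
                if isinstance(inner.term, Variable)
                else _BNODE_PREFIX + inner.term.label
            )
            term = sol.get(key)
            if isinstance(term, Literal):
                if term.datatype is not None:
                    return term.datatype
                return XSD.langString if term.language else XSD.string
        raise _FilterError("DATATYPE expects a literal-valued variable")
    if name == "CONTAINS":
        return _string_of(arg(1)) in _string_of(arg(0))
    if name == "STRSTARTS":
        return _string_of(arg(0)).startswith(_string_of(arg(1)))
    if name == "STRENDS":
        return _string_of(arg(0)).endswith(_string_of(arg(1)))
    if name == "ISIRI":
        return isinstance(arg(0), IRI)
    if name == "ISLITERAL":
        value = arg(0)
        return isinstance(value, (str, int, float, bool)) and not isinstance(value, IRI)
    if name == "ISBLANK":
        return isinstance(arg(0), BlankNode)
    if name == "LCASE":
        return _string_of(arg(0)).lower()
    if name == "UCASE":
        return _string_of(arg(0)).upper()
    if name == "STRLEN":
        return len(_string_of(arg(0)))
    raise _FilterError(f"unsupported function {name}")
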