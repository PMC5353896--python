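"""SPARQL 1.1 rewriting: exclusive groups into SERVICE blocks, the rest into
UNIONs of SERVICE blocks.

An *exclusive group* of a BGP, for dataset D, is the set of its triple
patterns whose relevance set is exactly {D}.  Those patterns can be shipped to
D as one conjunctive sub-query — no other source can contribute to them, so
executing the join remotely is correct and avoids transferring intermediate
results.  Every remaining pattern (relevant to two or more datasets) becomes a
UNION over one SERVICE block per relevant source.  The surrounding OPTIONAL /
FILTER / UNION structure and the solution modifiers of the original query are
preserved; a filter is pushed inside a SERVICE block when that block is the
only one binding all of the filter's variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .algebra import (
    BGPNode,
    BasicGraphPattern,
    Expr,
    FilterNode,
    Join,
    LeftJoin,
    Node,
    ParsedQuery,
    ServiceNode,
    TermExpr,
    TriplePattern,
    UnionNode,
    expr_variables,
    pattern_variables,
    serialize_query,
    walk_nodes,
)
from .catalogue import Catalogue
from .selection import RelevanceSets
from .terms import IRI, Literal, XSD

__all__ = ["ExclusiveGroup", "RewrittenQuery", "RewriteError", "exclusive_groups", "rewrite"]


class RewriteError(RuntimeError):
    pass


@dataclass(frozen=True)
class ExclusiveGroup:
    """Patterns of one BGP whose single relevant source is ``dataset_id``."""

    dataset_id: IRI
    bgp_id: int
    patterns: Tuple[TriplePattern, ...]

    @property
    def min_ordinal(self) -> int:
        return min(tp.ordinal for tp in self.patterns)


@dataclass
class RewrittenQuery:
    text: str
    query: ParsedQuery
    blocks: List[dict] = field(default_factory=list)
    endpoint_of: Dict[IRI, str] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)

    def block_patterns(self) -> List[TriplePattern]:
        """Each input pattern once, as placed in blocks: an exclusive group
        contributes its members, a UNION block contributes its single pattern
        (replicated across branches in the tree, counted once here)."""
        out: List[TriplePattern] = []
        for block in self.blocks:
            if block["kind"] == "exclusive":
                out.extend(block["patterns"])
            else:
                out.append(block["pattern"])
        return out


def exclusive_groups(bgp: BasicGraphPattern, relevance: RelevanceSets) -> List[ExclusiveGroup]:
    """Partition the BGP's singleton-relevance patterns by their sole dataset."""
    by_dataset: Dict[IRI, List[TriplePattern]] = {}
    for tp in bgp:
        rel = relevance.per_pattern.get(tp.key)
        if rel is None:
            raise RewriteError(f"no relevance set for pattern {tp.key}")
        if len(rel) == 1:
            (dataset,) = rel
            by_dataset.setdefault(dataset, []).append(tp)
    groups = [
        ExclusiveGroup(dataset_id=ds, bgp_id=bgp.id, patterns=tuple(tps))
        for ds, tps in by_dataset.items()
    ]
    groups.sort(key=lambda g: g.min_ordinal)
    return groups


_FALSE = TermExpr(Literal("false", datatype=XSD.boolean))


def rewrite(
    q: ParsedQuery,
    relevance: RelevanceSets,
    catalogue: Catalogue,
    statuses: Optional[Sequence] = None,
    group: bool = True,
    strict: bool = False,
) -> RewrittenQuery:
    """Rewrite a parsed query into federated SPARQL 1.1 text.

    ``statuses`` (a list of :class:`~sparqlfed.runtime.EndpointStatus`) enables
    lowest-latency mirror choice; without it each dataset's primary endpoint
    URL is used.  ``group=False`` disables exclusive grouping (one SERVICE per
    pattern), which changes block count but never results.  ``strict`` turns a
    pattern with an empty relevance set into a failure instead of an
    empty-solution block.
    """
    endpoint_of: Dict[IRI, str] = {}
    blocks: List[dict] = []
    warnings: List[str] = []

    def endpoint_for(dataset: IRI) -> str:
        if dataset not in endpoint_of:
            descriptor = catalogue.descriptors.get(dataset)
            if descriptor is None:
                raise RewriteError(f"dataset {dataset.value} is not in the catalogue")
            if statuses is not None:
                from .runtime import select_mirror

                endpoint_of[dataset] = select_mirror(descriptor, statuses)
            else:
                if not descriptor.endpoint_urls:
                    raise RewriteError(f"dataset {dataset.value} has no endpoint URL")
                endpoint_of[dataset] = descriptor.endpoint_urls[0]
        return endpoint_of[dataset]

    def rewrite_bgp(node: BGPNode) -> Node:
        bgp = node.bgp
        if not bgp.patterns:
            return node
        items: List[Tuple[int, Node]] = []
        grouped: Set[Tuple[int, int]] = set()
        if group:
            for eg in exclusive_groups(bgp, relevance):
                url = endpoint_for(eg.dataset_id)
                service = ServiceNode(IRI(url), BGPNode(BasicGraphPattern(bgp.id, eg.patterns)))
                items.append((eg.min_ordinal, service))
                grouped.update(tp.key for tp in eg.patterns)
                blocks.append(
                    {
                        "kind": "exclusive",
                        "dataset": eg.dataset_id,
                        "endpoint": url,
                        "patterns": list(eg.patterns),
                    }
                )
        for tp in bgp:
            if tp.key in grouped:
                continue
            rel = relevance.per_pattern.get(tp.key)
            if rel is None:
                raise RewriteError(f"no relevance set for pattern {tp.key}")
            if not rel:
                message = f"pattern {tp.key} has no relevant source; it can yield no solutions"
                if strict:
                    raise RewriteError(message)
                warnings.append(message)
                items.append((tp.ordinal, FilterNode(_FALSE, BGPNode(BasicGraphPattern(bgp.id, ())))))
                blocks.append({"kind": "empty", "pattern": tp})
                continue
            branches: List[Node] = []
            members: List[Tuple[IRI, str]] = []
            for ds in sorted(rel, key=lambda d: d.value):
                url = endpoint_for(ds)
                branches.append(ServiceNode(IRI(url), BGPNode(BasicGraphPattern(bgp.id, (tp,)))))
                members.append((ds, url))
            node_out: Node = branches[0] if len(branches) == 1 else UnionNode(branches)
            items.append((tp.ordinal, node_out))
            blocks.append({"kind": "union", "pattern": tp, "sources": members})
        items.sort(key=lambda pair: pair[0])
        parts = [n for _, n in items]
        return parts[0] if len(parts) == 1 else Join(parts)

    def rebuild(node: Node) -> Node:
        if isinstance(node, BGPNode):
            return rewrite_bgp(node)
        if isinstance(node, Join):
            return Join([rebuild(p) for p in node.parts])
        if isinstance(node, UnionNode):
            return UnionNode([rebuild(b) for b in node.branches])
        if isinstance(node, LeftJoin):
            return LeftJoin(rebuild(node.left), rebuild(node.right))
        if isinstance(node, ServiceNode):
            return ServiceNode(node.endpoint, rebuild(node.child), node.silent)
        if isinstance(node, FilterNode):
            child = rebuild(node.child)
            pushed = _try_push_filter(node.expr, child)
            return child if pushed else FilterNode(node.expr, child)
        raise TypeError(f"unknown algebra node {node!r}")

    root = rebuild(q.root)
    rewritten = ParsedQuery(
        form=q.form,
        root=root,
        projection=list(q.projection) if q.projection is not None else None,
        distinct=q.distinct,
        limit=q.limit,
        offset=q.offset,
        order_by=list(q.order_by),
        prefixes=dict(q.prefixes),
    )
    text = serialize_query(rewritten)
    rewritten.original_text = text
    return RewrittenQuery(
        text=text,
        query=rewritten,
        blocks=blocks,
        endpoint_of=endpoint_of,
        warnings=warnings,
    )


def _try_push_filter(expr: Expr, node: Node) -> bool:
    """Push a filter inside the single SERVICE block binding all its variables.

    Returns True when the filter was placed; the caller then drops the outer
    FILTER.  Conservative: only exclusive (non-UNION) service blocks qualify,
    and only when exactly one of them covers every filter variable.
    """
    wanted = expr_variables(expr)
    if not wanted:
        return False
    candidates: List[ServiceNode] = []

    def collect(n: Node, under_union: bool) -> None:
        if isinstance(n, ServiceNode) and not under_union:
            covered: Set[str] = set()
            for inner in walk_nodes(n.child):
                if isinstance(inner, BGPNode):
                    for tp in inner.bgp.patterns:
                        covered |= pattern_variables(tp)
            if wanted <= covered:
                candidates.append(n)
            return
        if isinstance(n, Join):
            for p in n.parts:
                collect(p, under_union)
        elif isinstance(n, UnionNode):
            for b in n.branches:
                collect(b, True)
        elif isinstance(n, FilterNode):
            collect(n.child, under_union)
        # LeftJoin boundaries are never crossed when pushing filters

    collect(node, False)
    if len(candidates) != 1:
        return False
    service = candidates[0]
    service.child = FilterNode(expr, service.child)
    return True
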