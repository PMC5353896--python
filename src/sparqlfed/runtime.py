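"""Federated execution with per-service provenance and endpoint monitoring.

Each SERVICE invocation is wrapped in an instrumentation contract: timestamp
before the call, timestamp after, count of solution rows returned, and an
ok/error/down status ("number of triples returned" is read as solution rows —
SERVICE returns bindings, not triples).  The per-query provenance record is
kept in a store with a wall-clock retention window (default 10 minutes) and is
also evicted when the same session executes its next query; the clock is
injectable so expiry is unit-testable.

Endpoint availability is probed preemptively with a trivial ASK; the resulting
statuses are mirrored into an RDF graph (the endpoint-data graph) so that the
health records themselves are queryable with SPARQL.  Mirror selection picks
the live endpoint with the lowest measured latency, breaking ties
lexicographically by URL.
"""

from __future__ import annotations

import time
import uuid
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

from .algebra import ParsedQuery, ServiceNode, serialize_node
from .catalogue import DatasetDescriptor
from .endpoints import EndpointRegistry, EndpointUnreachable
from .eval import Solution, evaluate_node, evaluate_query
from .graph import Graph
from .parser import parse_query
from .terms import IRI, Literal, Namespace, XSD

__all__ = [
    "ServiceProvenance",
    "QueryProvenance",
    "ProvenanceStore",
    "ProvenanceNotFound",
    "EndpointStatus",
    "AvailabilityMonitor",
    "check_availability",
    "select_mirror",
    "NoLiveEndpointError",
    "execute",
]

EPD = Namespace("urn:x-endpoint-data:")

DEFAULT_RETENTION_S = 600.0  # provenance kept 10 minutes


@dataclass
class ServiceProvenance:
    endpoint: str
    start_ms: float
    end_ms: float
    result_count: int
    status: str  # ok | error | down
    message: Optional[str] = None

    @property
    def elapsed_ms(self) -> float:
        return self.end_ms - self.start_ms

    def __post_init__(self) -> None:
        if self.end_ms < self.start_ms:
            raise ValueError("service record ends before it starts")
        if self.status != "ok" and not self.message:
            raise ValueError("non-ok service record requires a message")


@dataclass
class QueryProvenance:
    query_id: str
    services: List[ServiceProvenance] = field(default_factory=list)
    total_elapsed_ms: float = 0.0
    created_at: float = 0.0  # clock seconds
    retention_deadline: float = 0.0

    @property
    def result_counts(self) -> List[int]:
        return [s.result_count for s in self.services]

    def down_endpoints(self) -> List[str]:
        return [s.endpoint for s in self.services if s.status == "down"]


class ProvenanceNotFound(KeyError):
    def __init__(self, query_id: str) -> None:
        super().__init__(f"no provenance retained for query {query_id!r}")
        self.query_id = query_id


class ProvenanceStore:
    """Retains one provenance record per query, 10 minutes or until the same
    session runs its next query."""

    def __init__(
        self,
        clock: Callable[[], float] = time.time,
        retention_s: float = DEFAULT_RETENTION_S,
    ) -> None:
        self.clock = clock
        self.retention_s = retention_s
        self._records: Dict[str, QueryProvenance] = {}
        self._by_session: Dict[str, str] = {}

    def put(self, prov: QueryProvenance, session: str = "default") -> None:
        previous = self._by_session.get(session)
        if previous is not None:
            self._records.pop(previous, None)
        now = self.clock()
        prov.created_at = now
        prov.retention_deadline = now + self.retention_s
        self._records[prov.query_id] = prov
        self._by_session[session] = prov.query_id

    def get(self, query_id: str) -> QueryProvenance:
        prov = self._records.get(query_id)
        if prov is None or self.clock() > prov.retention_deadline:
            self._records.pop(query_id, None)
            raise ProvenanceNotFound(query_id)
        return prov


# ---------------------------------------------------------------------------
# Execution


def _subquery_text(node: ServiceNode) -> str:
    body = serialize_node(node.child, prefixes=None, indent=1)
    return f"SELECT * WHERE {{\n{body}\n}}"


def execute(
    rq: Union["RewrittenQueryLike", ParsedQuery, str],
    registry: EndpointRegistry,
    session: str = "default",
    store: Optional[ProvenanceStore] = None,
    clock: Callable[[], float] = time.time,
    strict: bool = False,
    query_id: Optional[str] = None,
) -> Tuple[List[Solution], QueryProvenance]:
    """Execute a (rewritten) query against the endpoint registry.

    Returns the solution multiset and the provenance record, which carries one
    :class:`ServiceProvenance` per SERVICE invocation in plan order.  With
    ``strict=False`` an endpoint failing mid-query contributes no solutions
    and a ``down`` record (partial results); ``strict=True`` aborts.
    """
    if isinstance(rq, str):
        query = parse_query(rq)
    elif isinstance(rq, ParsedQuery):
        query = rq
    else:
        query = rq.query  # RewrittenQuery
    prov = QueryProvenance(query_id=query_id or uuid.uuid4().hex)

    def handler(node: ServiceNode) -> List[Solution]:
        endpoint = registry.resolve(node.endpoint.value)
        text = _subquery_text(node)
        start = clock() * 1000
        try:
            rows = endpoint.select(text)
        except EndpointUnreachable as exc:
            end = clock() * 1000
            prov.services.append(
                ServiceProvenance(
                    endpoint=node.endpoint.value,
                    start_ms=start,
                    end_ms=max(end, start),
                    result_count=0,
                    status="down",
                    message=str(exc),
                )
            )
            if strict:
                raise
            return []
        except Exception as exc:  # malformed subquery, decoding failure, ...
            end = clock() * 1000
            prov.services.append(
                ServiceProvenance(
                    endpoint=node.endpoint.value,
                    start_ms=start,
                    end_ms=max(end, start),
                    result_count=0,
                    status="error",
                    message=str(exc),
                )
            )
            if strict:
                raise
            return []
        end = clock() * 1000
        prov.services.append(
            ServiceProvenance(
                endpoint=node.endpoint.value,
                start_ms=start,
                end_ms=max(end, start),
                result_count=len(rows),
                status="ok",
            )
        )
        return rows

    t0 = time.perf_counter()
    if query.form == "ASK":
        solutions_or_bool = bool(evaluate_node(query.root, graph=None, service_handler=handler))
        solutions: List[Solution] = [{}] if solutions_or_bool else []
    else:
        solutions = evaluate_query(query, graph=None, service_handler=handler)
    prov.total_elapsed_ms = (time.perf_counter() - t0) * 1000
    if prov.services:
        prov.total_elapsed_ms = max(
            prov.total_elapsed_ms, max(s.elapsed_ms for s in prov.services)
        )
    if store is not None:
        store.put(prov, session=session)
    return solutions, prov


# ---------------------------------------------------------------------------
# Availability monitoring


@dataclass
class EndpointStatus:
    url: str
    latency_ms: Optional[float]  # None when down (latency unknown)
    up: bool
    initialized: bool
    last_checked: float

    def __post_init__(self) -> None:
        if not self.up:
            self.latency_ms = None


class NoLiveEndpointError(RuntimeError):
    def __init__(self, dataset: str) -> None:
        super().__init__(f"no live endpoint for dataset {dataset}")
        self.dataset = dataset


class AvailabilityMonitor:
    """Tracks endpoint health and exposes it as a queryable RDF graph."""

    def __init__(self, clock: Callable[[], float] = time.time) -> None:
        self.clock = clock
        self.statuses: Dict[str, EndpointStatus] = {}
        self.endpoint_data = Graph()

    def check(self, urls: Sequence[str], registry: EndpointRegistry) -> List[EndpointStatus]:
        out: List[EndpointStatus] = []
        for url in urls:
            checked_at = self.clock()
            previous = self.statuses.get(url)
            if previous is not None:
                checked_at = max(checked_at, previous.last_checked)
            try:
                endpoint = registry.resolve(url)
                t0 = time.perf_counter()
                endpoint.ask("ASK { }")  # any answer at all means reachable
                latency = (time.perf_counter() - t0) * 1000
                latency += getattr(endpoint, "extra_latency_ms", 0.0)
                status = EndpointStatus(
                    url=url,
                    latency_ms=latency,
                    up=True,
                    initialized=True,
                    last_checked=checked_at,
                )
            except Exception:
                status = EndpointStatus(
                    url=url,
                    latency_ms=None,
                    up=False,
                    initialized=previous.initialized if previous else False,
                    last_checked=checked_at,
                )
            self.statuses[url] = status
            out.append(status)
        self._rebuild_graph()
        return out

    def _rebuild_graph(self) -> None:
        g = Graph()
        for url, st in self.statuses.items():
            node = IRI(url)
            g.add(node, EPD.url, Literal(url))
            g.add(node, EPD.up, Literal("true" if st.up else "false", datatype=XSD.boolean))
            g.add(
                node,
                EPD.initialized,
                Literal("true" if st.initialized else "false", datatype=XSD.boolean),
            )
            if st.latency_ms is not None:
                g.add(node, EPD.latencyMs, Literal(repr(st.latency_ms), datatype=XSD.double))
            g.add(node, EPD.lastChecked, Literal(repr(st.last_checked), datatype=XSD.double))
        self.endpoint_data = g


def check_availability(
    urls: Sequence[str],
    registry: EndpointRegistry,
    monitor: Optional[AvailabilityMonitor] = None,
) -> List[EndpointStatus]:
    """Probe each URL with a trivial ASK, updating the endpoint-data graph."""
    monitor = monitor or AvailabilityMonitor()
    return monitor.check(urls, registry)


def select_mirror(descriptor: DatasetDescriptor, statuses: Sequence[EndpointStatus]) -> str:
    """Lowest-latency live mirror of a dataset; lexicographic URL tie-break."""
    if not descriptor.endpoint_urls:
        raise NoLiveEndpointError(descriptor.dataset_id.value)
    by_url = {s.url: s for s in statuses}
    live = [
        (by_url[url].latency_ms, url)
        for url in descriptor.endpoint_urls
        if url in by_url and by_url[url].up and by_url[url].latency_ms is not None
    ]
    if not live:
        raise NoLiveEndpointError(descriptor.dataset_id.value)
    live.sort(key=lambda pair: (pair[0], pair[1]))
    return live[0][1]


RewrittenQueryLike = object  # structural: anything with a .query ParsedQuery
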