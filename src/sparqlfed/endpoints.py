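"""Endpoint abstraction: in-process graphs and remote HTTP SPARQL services.

Every endpoint speaks SPARQL *text* through ``select``/``ask``, whether it is a
wrapped in-memory graph or a remote SPARQL-protocol service.  The federation
runtime, source selection and catalogue probing are therefore identical for
both; tests run entirely against in-process endpoints while a deployment can
register HTTP ones.
"""

from __future__ import annotations

import json
import time
import urllib.error
import urllib.parse
import urllib.request
from typing import Dict, List, Optional, Protocol, runtime_checkable

from .eval import Solution, evaluate_ask, evaluate_query
from .graph import Graph
from .parser import parse_query
from .terms import IRI, BlankNode, Literal, Term

__all__ = [
    "Endpoint",
    "GraphEndpoint",
    "HttpEndpoint",
    "EndpointRegistry",
    "EndpointUnreachable",
    "UnknownEndpointError",
]


class EndpointUnreachable(RuntimeError):
    """The endpoint did not answer (network failure or administratively down)."""

    def __init__(self, url: str, reason: str = "endpoint down") -> None:
        super().__init__(f"{reason}: {url}")
        self.url = url


class UnknownEndpointError(KeyError):
    def __init__(self, url: str) -> None:
        super().__init__(f"no endpoint registered for {url}")
        self.url = url


@runtime_checkable
class Endpoint(Protocol):
    def select(self, query_text: str) -> List[Solution]: ...

    def ask(self, query_text: str) -> bool: ...


class GraphEndpoint:
    """An in-process SPARQL endpoint over a local graph.

    ``down`` simulates an unreachable service; ``extra_latency_ms`` is added to
    measured probe latencies so mirror selection is testable deterministically.
    """

    def __init__(
        self,
        graph: Graph,
        url: str = "",
        down: bool = False,
        extra_latency_ms: float = 0.0,
    ) -> None:
        self.graph = graph
        self.url = url
        self.down = down
        self.extra_latency_ms = extra_latency_ms

    def _check_up(self) -> None:
        if self.down:
            raise EndpointUnreachable(self.url or "<in-process>")

    def select(self, query_text: str) -> List[Solution]:
        self._check_up()
        q = parse_query(query_text)
        if q.form != "SELECT":
            raise ValueError("select() requires a SELECT query")
        return evaluate_query(q, graph=self.graph)

    def ask(self, query_text: str) -> bool:
        self._check_up()
        q = parse_query(query_text)
        if q.form != "ASK":
            raise ValueError("ask() requires an ASK query")
        return evaluate_ask(q, graph=self.graph)


class HttpEndpoint:
    """A remote endpoint speaking the SPARQL 1.1 protocol over HTTP POST.

    Results are read from the ``application/sparql-results+json`` format.
    Untested against live services in this repository (no network in the test
    environment); the JSON decoding is exercised separately.
    """

    def __init__(self, url: str, timeout_s: float = 60.0) -> None:
        self.url = url
        self.timeout_s = timeout_s

    def _request(self, query_text: str) -> dict:
        data = urllib.parse.urlencode({"query": query_text}).encode()
        req = urllib.request.Request(
            self.url,
            data=data,
            headers={
                "Accept": "application/sparql-results+json",
                "Content-Type": "application/x-www-form-urlencoded",
            },
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout_s) as resp:
                return json.loads(resp.read().decode("utf-8"))
        except (urllib.error.URLError, OSError, ValueError) as exc:
            raise EndpointUnreachable(self.url, reason=str(exc)) from exc

    def select(self, query_text: str) -> List[Solution]:
        return decode_json_results(self._request(query_text))

    def ask(self, query_text: str) -> bool:
        payload = self._request(query_text)
        if "boolean" not in payload:
            raise EndpointUnreachable(self.url, reason="malformed ASK response")
        return bool(payload["boolean"])


def decode_json_results(payload: dict) -> List[Solution]:
    """Decode a SPARQL JSON results document into binding dicts."""
    out: List[Solution] = []
    for row in payload.get("results", {}).get("bindings", []):
        sol: Solution = {}
        for var, cell in row.items():
            sol[var] = _decode_cell(cell)
        out.append(sol)
    return out


def _decode_cell(cell: dict) -> Term:
    kind = cell.get("type")
    value = cell.get("value", "")
    if kind == "uri":
        return IRI(value)
    if kind == "bnode":
        return BlankNode(value)
    if kind in ("literal", "typed-literal"):
        dt = cell.get("datatype")
        lang = cell.get("xml:lang")
        return Literal(value, datatype=IRI(dt) if dt else None, language=lang)
    raise ValueError(f"unknown binding type {kind!r}")


class EndpointRegistry:
    """Maps endpoint URLs to query capabilities."""

    def __init__(self, resolvers: Optional[Dict[str, Endpoint]] = None) -> None:
        self.resolvers: Dict[str, Endpoint] = dict(resolvers or {})

    def register(self, url: str, endpoint: Endpoint) -> None:
        self.resolvers[url] = endpoint

    def deregister(self, url: str) -> None:
        self.resolvers.pop(url, None)

    def resolve(self, url: str) -> Endpoint:
        try:
            return self.resolvers[url]
        except KeyError:
            raise UnknownEndpointError(url) from None

    def __contains__(self, url: str) -> bool:
        return url in self.resolvers

    def urls(self) -> List[str]:
        return list(self.resolvers)
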