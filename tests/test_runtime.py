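"""Execution provenance, retention, availability monitoring, mirrors."""

import pytest

from sparqlfed import (
    AvailabilityMonitor,
    EndpointRegistry,
    EndpointStatus,
    Graph,
    GraphEndpoint,
    IRI,
    ProvenanceNotFound,
    ProvenanceStore,
    execute,
    parse_query,
    rewrite,
    select_mirror,
    select_sources,
)
from sparqlfed.algebra import ServiceNode, walk_nodes
from sparqlfed.catalogue import DatasetDescriptor
from sparqlfed.runtime import NoLiveEndpointError, _subquery_text


class FakeClock:
    def __init__(self, start=1000.0):
        self.now = start

    def __call__(self):
        return self.now

    def tick(self, seconds):
        self.now += seconds


def _rewritten(worked_fed, worked_query):
    rel, _ = select_sources(worked_query, worked_fed.catalogue, worked_fed.asker())
    return rewrite(worked_query, rel, worked_fed.catalogue)


def test_one_provenance_record_per_service_invocation(worked_fed, worked_query):
    rq = _rewritten(worked_fed, worked_query)
    sols, prov = execute(rq, worked_fed.registry)
    n_services = sum(1 for n in walk_nodes(rq.query.root) if isinstance(n, ServiceNode))
    assert len(prov.services) == n_services == 4
    assert all(s.status == "ok" for s in prov.services)
    assert all(s.elapsed_ms >= 0 for s in prov.services)
    assert prov.total_elapsed_ms >= max(s.elapsed_ms for s in prov.services)


def test_result_count_equals_independent_block_evaluation(worked_fed, worked_query):
    rq = _rewritten(worked_fed, worked_query)
    _, prov = execute(rq, worked_fed.registry)
    services = [n for n in walk_nodes(rq.query.root) if isinstance(n, ServiceNode)]
    for node, record in zip(services, prov.services):
        assert record.endpoint == node.endpoint.value
        independent = worked_fed.registry.resolve(node.endpoint.value).select(
            _subquery_text(node)
        )
        assert record.result_count == len(independent)


def test_empty_registry_graphs_give_zero_counts(worked_fed, worked_query):
    rq = _rewritten(worked_fed, worked_query)
    empty_registry = EndpointRegistry(
        {url: GraphEndpoint(Graph(), url=url) for url in worked_fed.registry.urls()}
    )
    sols, prov = execute(rq, empty_registry)
    assert sols == []
    assert all(s.result_count == 0 for s in prov.services)


def test_retention_expiry_and_session_eviction(worked_fed, worked_query):
    rq = _rewritten(worked_fed, worked_query)
    clock = FakeClock()
    store = ProvenanceStore(clock=clock)
    _, prov1 = execute(rq, worked_fed.registry, session="alice", store=store, clock=clock)
    assert store.get(prov1.query_id) is prov1
    # expires after the 10-minute retention window
    clock.tick(601)
    with pytest.raises(ProvenanceNotFound):
        store.get(prov1.query_id)
    # evicted by the same session's next query, even within the window
    _, prov2 = execute(rq, worked_fed.registry, session="alice", store=store, clock=clock)
    clock.tick(1)
    _, prov3 = execute(rq, worked_fed.registry, session="alice", store=store, clock=clock)
    with pytest.raises(ProvenanceNotFound):
        store.get(prov2.query_id)
    assert store.get(prov3.query_id) is prov3
    # a different session does not evict
    _, prov4 = execute(rq, worked_fed.registry, session="bob", store=store, clock=clock)
    assert store.get(prov3.query_id) is prov3


def test_down_endpoint_yields_partial_results_and_one_down_record(
    worked_fed, worked_query
):
    rq = _rewritten(worked_fed, worked_query)
    registry = EndpointRegistry(dict(worked_fed.registry.resolvers))
    chebi_url = "http://chebi.example/sparql"
    registry.register(chebi_url, GraphEndpoint(Graph(), url=chebi_url, down=True))
    sols, prov = execute(rq, registry)
    down = [s for s in prov.services if s.status == "down"]
    assert len(down) == 1 and down[0].endpoint == chebi_url
    assert down[0].message
    assert sols  # KEGG union branch still answers: partial, not empty
    from sparqlfed.endpoints import EndpointUnreachable

    with pytest.raises(EndpointUnreachable):
        execute(rq, registry, strict=True)


def test_check_availability_and_endpoint_data_readback(worked_fed):
    monitor = AvailabilityMonitor()
    urls = ["http://kegg.example/sparql", "http://unregistered.example/sparql"]
    statuses = monitor.check(urls, worked_fed.registry)
    assert statuses[0].up and statuses[0].latency_ms >= 0 and statuses[0].initialized
    assert not statuses[1].up and statuses[1].latency_ms is None
    # the endpoint-data graph answers SPARQL about exactly these statuses
    ep = GraphEndpoint(monitor.endpoint_data)
    rows = ep.select(
        "SELECT ?e ?up WHERE { ?e <urn:x-endpoint-data:up> ?up . }"
    )
    got = {r["e"].value: r["up"].lexical == "true" for r in rows}
    assert got == {s.url: s.up for s in statuses}


def test_last_checked_is_monotone(worked_fed):
    clock = FakeClock()
    monitor = AvailabilityMonitor(clock=clock)
    url = "http://kegg.example/sparql"
    first = monitor.check([url], worked_fed.registry)[0]
    clock.tick(-5)  # a clock hiccup must not move last_checked backwards
    second = monitor.check([url], worked_fed.registry)[0]
    assert second.last_checked >= first.last_checked


def test_select_mirror_lowest_latency_and_failover():
    d = DatasetDescriptor(
        dataset_id=IRI("http://fed.example/dataset/kegg"),
        endpoint_urls=["http://a.example/sparql", "http://b.example/sparql"],
    )
    s = lambda url, up, lat: EndpointStatus(url=url, latency_ms=lat, up=up, initialized=True, last_checked=0.0)
    assert (
        select_mirror(d, [s("http://a.example/sparql", True, 50.0), s("http://b.example/sparql", True, 10.0)])
        == "http://b.example/sparql"
    )
    # tie on latency: lexicographic URL
    assert (
        select_mirror(d, [s("http://b.example/sparql", True, 10.0), s("http://a.example/sparql", True, 10.0)])
        == "http://a.example/sparql"
    )
    # only live candidate wins regardless of latency
    assert (
        select_mirror(d, [s("http://a.example/sparql", True, 99.0), s("http://b.example/sparql", False, None)])
        == "http://a.example/sparql"
    )
    with pytest.raises(NoLiveEndpointError):
        select_mirror(d, [s("http://a.example/sparql", False, None)])


def test_rewrite_uses_lowest_latency_mirror(worked_fed, worked_query):
    rel, _ = select_sources(worked_query, worked_fed.catalogue, worked_fed.asker())
    drugbank = worked_fed.catalogue.descriptors[worked_fed.dataset("drugbank")]
    primary, mirror = drugbank.endpoint_urls
    statuses = [
        EndpointStatus(url=primary, latency_ms=80.0, up=True, initialized=True, last_checked=0.0),
        EndpointStatus(url=mirror, latency_ms=5.0, up=True, initialized=True, last_checked=0.0),
    ]
    # every other dataset keeps its primary
    for did, desc in worked_fed.catalogue.descriptors.items():
        if did != worked_fed.dataset("drugbank"):
            statuses.append(
                EndpointStatus(url=desc.endpoint_urls[0], latency_ms=1.0, up=True, initialized=True, last_checked=0.0)
            )
    rq = rewrite(worked_query, rel, worked_fed.catalogue, statuses=statuses)
    assert rq.endpoint_of[worked_fed.dataset("drugbank")] == mirror
    sols, _ = execute(rq, worked_fed.registry)
    assert sols
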