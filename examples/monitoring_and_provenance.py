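"""Endpoint health monitoring, mirror selection and provenance retention.

Probes every registered endpoint with a trivial ASK, queries the resulting
endpoint-data graph with SPARQL, picks the lowest-latency mirror for a
dataset, and demonstrates the provenance store's 10-minute retention and
next-query eviction using an injected clock.
"""

from sparqlfed import (
    AvailabilityMonitor,
    GraphEndpoint,
    ProvenanceNotFound,
    ProvenanceStore,
    execute,
    parse_query,
    rewrite,
    select_mirror,
    select_sources,
    worked_example_fixture,
)
from sparqlfed.synthetic import WORKED_EXAMPLE_QUERY

fed = worked_example_fixture()

# deterministic latencies for the demo: the mirror is made faster
kegg = fed.dataset("kegg")
primary, mirror = fed.catalogue.descriptors[kegg].endpoint_urls
fed.registry.resolve(primary).extra_latency_ms = 40.0
fed.registry.resolve(mirror).extra_latency_ms = 2.0

monitor = AvailabilityMonitor()
statuses = monitor.check(fed.registry.urls(), fed.registry)
print("Endpoint health (first 5):")
for status in statuses[:5]:
    latency = f"{status.latency_ms:.2f} ms" if status.up else "unknown"
    print(f"  {status.url}: up={status.up} latency={latency}")

rows = GraphEndpoint(monitor.endpoint_data).select(
    "SELECT ?e ?l WHERE { ?e <urn:x-endpoint-data:latencyMs> ?l . }"
)
print(f"\nThe endpoint-data graph answers SPARQL: {len(rows)} latency records.")

chosen = select_mirror(fed.catalogue.descriptors[kegg], statuses)
print(f"\nLowest-latency mirror for kegg: {chosen}")
print("(the mirror wins because its measured latency is lower)")

# provenance retention with an injected clock
now = [0.0]
clock = lambda: now[0]
store = ProvenanceStore(clock=clock)
query = parse_query(WORKED_EXAMPLE_QUERY)
relevance, _ = select_sources(query, fed.catalogue, fed.asker())
rewritten = rewrite(query, relevance, fed.catalogue)
_, prov = execute(rewritten, fed.registry, session="alice", store=store, clock=clock)
print(f"\nStored provenance {prov.query_id[:8]}… with {len(prov.services)} service records.")
now[0] += 601
try:
    store.get(prov.query_id)
except ProvenanceNotFound:
    print("After 10 minutes the record has expired (retention window).")
_, p1 = execute(rewritten, fed.registry, session="alice", store=store, clock=clock)
_, p2 = execute(rewritten, fed.registry, session="alice", store=store, clock=clock)
try:
    store.get(p1.query_id)
except ProvenanceNotFound:
    print("A session's next query evicts its previous record immediately.")
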