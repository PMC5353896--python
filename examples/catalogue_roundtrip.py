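"""Probing an endpoint into a VoID catalogue and reading it back.

Probes an enzyme-database-style graph, prints the resulting descriptor,
persists the catalogue as VoID/Turtle and shows that the read-back descriptors
and the predicate index survive the round trip.
"""

import os
import tempfile

from sparqlfed import (
    Catalogue,
    Graph,
    GraphEndpoint,
    IRI,
    Literal,
    derive_uri_pattern,
    probe_endpoint,
    read_catalogue,
    write_catalogue,
)
from sparqlfed.terms import RDF

ns = "http://bio2rdf.example/ns/kegg#"
graph = Graph()
enzyme = IRI("http://bio2rdf.example/ec:3.2.1.161")
graph.add(enzyme, RDF.type, IRI(ns + "Enzyme"))
graph.add(enzyme, IRI(ns + "xSubstrate"), IRI("http://bio2rdf.example/cpd:C00001"))
graph.add(enzyme, IRI("http://bio2rdf.example/ns/bio2rdf#synonym"), Literal("beta-glucosidase"))
graph.add(IRI("http://bio2rdf.example/cpd:C00001"), RDF.type, IRI(ns + "Compound"))

descriptor = probe_endpoint(
    GraphEndpoint(graph),
    IRI("http://fed.example/dataset/kegg"),
    endpoint_urls=["http://kegg.example/sparql", "http://mirror1.kegg.example/sparql"],
    title="kegg",
)
print(f"Probed dataset '{descriptor.title}':")
for cls in descriptor.classes:
    print(f"  class {cls.class_iri.value}  example={cls.example_resources[0].value}")
    print(f"    uriRegexPattern: {cls.uri_regex_pattern}")
for pred in descriptor.predicates:
    rng = pred.range_class.local_name if pred.range_class else "-"
    print(f"  predicate {pred.predicate_iri.value}  (range class: {rng})")

print("\nPattern derived from an example resource generalizes the local id:")
print(" ", derive_uri_pattern("http://bio2rdf.example/ec:3.2.1.161"))

with tempfile.TemporaryDirectory() as tmp:
    path = os.path.join(tmp, "ardi.ttl")
    write_catalogue(Catalogue([descriptor]), path)
    print(f"\nVoID/Turtle ({path}):\n")
    print(open(path).read())
    back = read_catalogue(path)

restored = back.descriptors[descriptor.dataset_id]
print("Round trip lossless:", restored == descriptor)
print("Mirror URLs preserved in order:", restored.endpoint_urls)
lookup = back.predicate_lookup(IRI(ns + "xSubstrate"))
print("predicate_lookup(kegg#xSubstrate):", sorted(d.value for d in lookup))
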