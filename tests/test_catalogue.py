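"""Catalogue probing, URI pattern derivation, VoID round trips, lookups."""

import random
import re

import pytest

from sparqlfed import (
    Catalogue,
    DatasetDescriptor,
    Graph,
    GraphEndpoint,
    IRI,
    Literal,
    derive_uri_pattern,
    probe_endpoint,
    read_catalogue,
    write_catalogue,
)
from sparqlfed.catalogue import CatalogueError, catalogue_to_graph
from sparqlfed.terms import RDF, VOID


def kegg_like_graph():
    g = Graph()
    ns = "http://bio2rdf.example/ns/kegg#"
    common = "http://bio2rdf.example/ns/bio2rdf#"
    enzyme = IRI("http://bio2rdf.example/ec:3.2.1.161")
    substrate = IRI("http://bio2rdf.example/cpd:C00001")
    g.add(enzyme, RDF.type, IRI(ns + "Enzyme"))
    g.add(enzyme, IRI(common + "synonym"), Literal("beta-glucosidase"))
    g.add(enzyme, IRI(ns + "xSubstrate"), substrate)
    g.add(enzyme, IRI(ns + "xGene"), IRI("http://bio2rdf.example/kegg:b0344"))
    g.add(substrate, RDF.type, IRI(ns + "Compound"))
    return g


def test_probe_records_classes_predicates_examples():
    g = kegg_like_graph()
    d = probe_endpoint(GraphEndpoint(g), IRI("http://fed.example/dataset/kegg"))
    class_iris = {c.class_iri.value for c in d.classes}
    assert "http://bio2rdf.example/ns/kegg#Enzyme" in class_iris
    # descriptor predicates equal a brute-force scan of the graph
    assert {p.predicate_iri for p in d.predicates} == set(g.predicates())
    enzyme_class = next(c for c in d.classes if c.class_iri.local_name == "Enzyme")
    assert enzyme_class.example_resources == [IRI("http://bio2rdf.example/ec:3.2.1.161")]
    assert enzyme_class.label == "Enzyme"
    assert re.match(enzyme_class.uri_regex_pattern, "http://bio2rdf.example/ec:1.1.1.1")
    # range class sampled from rdf:type of the object inside the same graph
    xsub = next(p for p in d.predicates if p.predicate_iri.local_name == "xSubstrate")
    assert xsub.range_class == IRI("http://bio2rdf.example/ns/kegg#Compound")
    assert xsub.domain_class == IRI("http://bio2rdf.example/ns/kegg#Enzyme")


def test_probe_empty_graph():
    d = probe_endpoint(GraphEndpoint(Graph()), IRI("http://fed.example/dataset/empty"))
    assert d.classes == [] and d.predicates == []
    assert d.partial is False


def test_probe_marks_partial_when_page_filled():
    from sparqlfed import ProbeBudget

    g = kegg_like_graph()
    d = probe_endpoint(
        GraphEndpoint(g),
        IRI("http://fed.example/dataset/kegg"),
        budget=ProbeBudget(page_size=2),
    )
    assert d.partial is True


def test_derive_uri_pattern_examples():
    p = derive_uri_pattern("http://bio2rdf.org/ec:3.2.1.161")
    assert p.startswith("^") and p.endswith("$")
    assert re.match(p, "http://bio2rdf.org/ec:3.2.1.161")
    assert re.match(p, "http://bio2rdf.org/ec:9.9.9.9")
    assert not re.match(p, "http://bio2rdf.org/cpd:C00001")
    # no local segment: exact match only
    exact = derive_uri_pattern("http://example.org/")
    assert re.match(exact, "http://example.org/")
    assert not re.match(exact, "http://example.org/x")


def test_every_iri_matches_its_own_derived_pattern():
    rng = random.Random(42)
    pieces = ["ec", "cpd", "kegg", "drug", "gene"]
    for _ in range(50):
        style = rng.randrange(3)
        local = "".join(rng.choice("abc123.") for _ in range(rng.randint(1, 8)))
        if style == 0:
            iri = f"http://bio2rdf.org/{rng.choice(pieces)}:{local}"
        elif style == 1:
            iri = f"http://ex.org/{rng.choice(pieces)}/{local}"
        else:
            iri = f"http://ex.org/{rng.choice(pieces)}#{local}"
        assert re.match(derive_uri_pattern(iri), iri), iri


def test_void_round_trip_is_lossless(worked_fed, tmp_path):
    path = str(tmp_path / "ardi.ttl")
    write_catalogue(worked_fed.catalogue, path)
    back = read_catalogue(path)
    assert set(back.descriptors) == set(worked_fed.catalogue.descriptors)
    for did, original in worked_fed.catalogue.descriptors.items():
        assert back.descriptors[did] == original  # field-by-field dataclass equality
    assert back.predicate_index == worked_fed.catalogue.predicate_index
    assert back.class_index == worked_fed.catalogue.class_index


def test_mirrors_emitted_as_multivalued_sparql_endpoint(worked_fed):
    g = catalogue_to_graph(worked_fed.catalogue)
    drugbank = worked_fed.dataset("drugbank")
    urls = [t.object.value for t in g.match(drugbank, VOID.sparqlEndpoint)]
    assert len(urls) == 2 and urls[0] != urls[1]
    assert urls == worked_fed.catalogue.descriptors[drugbank].endpoint_urls


def test_predicate_lookup(worked_fed):
    cat = worked_fed.catalogue
    drug_category = IRI("http://bio2rdf.example/ns/drugbank#drugCategory")
    assert cat.predicate_lookup(drug_category) == {worked_fed.dataset("drugbank")}
    assert cat.predicate_lookup(IRI("http://nowhere.example/p")) == set()
    assert cat.predicate_lookup(RDF.type) == set(worked_fed.dataset_ids)


def test_lookup_membership_matches_direct_ask(worked_fed):
    """Index membership for a bound predicate equals per-graph ASK."""
    for did, g in worked_fed.graphs.items():
        for pred in g.predicates():
            assert did in worked_fed.catalogue.predicate_lookup(pred)
    for pred, datasets in worked_fed.catalogue.predicate_index.items():
        for did in datasets:
            assert worked_fed.graphs[did].ask(None, pred, None)


def test_duplicate_dataset_rejected():
    d = DatasetDescriptor(dataset_id=IRI("http://d"), endpoint_urls=["http://u"])
    cat = Catalogue([d])
    with pytest.raises(CatalogueError, match="http://d"):
        cat.add(DatasetDescriptor(dataset_id=IRI("http://d"), endpoint_urls=["http://v"]))


def test_descriptor_without_endpoint_rejected():
    with pytest.raises(CatalogueError):
        Catalogue([DatasetDescriptor(dataset_id=IRI("http://d"))])
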