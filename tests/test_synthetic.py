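"""Synthetic federation generator: determinism, ground truth, agreement."""

import random

import pytest

from sparqlfed import IRI, TopologyConfig, Variable, generate, probe_endpoint
from sparqlfed.algebra import TriplePattern
from sparqlfed.endpoints import GraphEndpoint
from sparqlfed.synthetic import (
    DEFAULT_DATASET_NAMES,
    load_topology,
    vocab_ns,
    worked_example_fixture,
)
from sparqlfed.terms import RDF, Literal


def test_same_seed_gives_byte_identical_graphs():
    cfg = TopologyConfig(n_datasets=4, instances_per_class=10, seed=99)
    a, b = generate(cfg), generate(cfg)
    for did in a.graphs:
        assert a.graphs[did].to_ntriples() == b.graphs[did].to_ntriples()
    assert generate(TopologyConfig(n_datasets=4, instances_per_class=10, seed=100)).graphs[
        did
    ].to_ntriples() != a.graphs[did].to_ntriples()


def test_exclusive_predicate_truth_is_its_dataset(small_fed):
    for did, name in small_fed.names.items():
        tp = TriplePattern(Variable("x"), vocab_ns(name)["x0"], Variable("y"))
        assert small_fed.truth(tp) == {did}


def test_shared_predicates_occur_everywhere(small_fed):
    tp = TriplePattern(Variable("x"), RDF.type, Variable("y"))
    assert small_fed.truth(tp) == set(small_fed.dataset_ids)


def test_truth_agrees_with_brute_force_on_500_probe_patterns(small_fed):
    rng = random.Random(2024)
    pool = []
    for did, g in small_fed.graphs.items():
        pool.extend(list(g))
    for _ in range(500):
        t = pool[rng.randrange(len(pool))]
        s = t.subject if rng.random() < 0.5 else Variable("s")
        p = t.predicate if rng.random() < 0.8 else Variable("p")
        o = t.object if rng.random() < 0.5 else Variable("o")
        tp = TriplePattern(s, p, o)
        expected = set()
        for did, g in small_fed.graphs.items():
            for x in g:
                if (
                    (not isinstance(s, Variable) and x.subject != s)
                    or (not isinstance(p, Variable) and x.predicate != p)
                    or (not isinstance(o, Variable) and x.object != o)
                ):
                    continue
                expected.add(did)
                break
        assert small_fed.truth(tp) == expected


def test_catalogue_matches_fresh_probe(small_fed):
    """The federation's catalogue equals probe_endpoint re-run on each graph."""
    for did, descriptor in small_fed.catalogue.descriptors.items():
        fresh = probe_endpoint(
            GraphEndpoint(small_fed.graphs[did], url=descriptor.endpoint_urls[0]),
            did,
            endpoint_urls=descriptor.endpoint_urls,
            title=descriptor.title,
        )
        assert fresh == descriptor


def test_literal_overlap_shares_values():
    fed = generate(TopologyConfig(seed=5))
    chebi = fed.graphs[fed.dataset("chebi")]
    drugbank = fed.graphs[fed.dataset("drugbank")]
    titles = {t.object.lexical for t in chebi.match(None, vocab_ns("chebi")["title"])}
    names = {t.object.lexical for t in drugbank.match(None, vocab_ns("drugbank")["genericName"])}
    assert titles & names  # the same literal values appear under both predicates


def test_cross_links_point_at_target_instances():
    fed = generate(TopologyConfig(seed=5))
    drugbank = fed.graphs[fed.dataset("drugbank")]
    links = list(drugbank.match(None, vocab_ns("drugbank")["keggCompoundId"]))
    assert links
    kegg = fed.graphs[fed.dataset("kegg")]
    assert all(kegg.ask(t.object, RDF.type, None) for t in links)


def test_remove_dataset_removes_truth(small_fed):
    fed = generate(TopologyConfig(n_datasets=4, instances_per_class=8, seed=3))
    victim = fed.dataset_ids[0]
    name = fed.names[victim]
    tp = TriplePattern(Variable("x"), vocab_ns(name)["x0"], Variable("y"))
    assert fed.truth(tp) == {victim}
    fed.remove_dataset(victim)
    assert fed.truth(tp) == set()
    assert victim not in fed.catalogue.descriptors


def test_invalid_config_rejected():
    with pytest.raises(ValueError, match="unknown dataset"):
        TopologyConfig(cross_links=(("drugbank", "nonexistent", "p"),)).validate()
    with pytest.raises(ValueError):
        TopologyConfig(n_datasets=0).validate()


def test_worked_fixture_constructed_relevance_profile(worked_fed):
    drugbank = worked_fed.dataset("drugbank")
    kegg = worked_fed.dataset("kegg")
    chebi = worked_fed.dataset("chebi")
    ns_db, ns_kegg = vocab_ns("drugbank"), vocab_ns("kegg")
    bio2rdf = vocab_ns("bio2rdf")
    assert worked_fed.truth(
        TriplePattern(Variable("d"), ns_db.drugCategory, Variable("c"))
    ) == {drugbank}
    assert worked_fed.truth(
        TriplePattern(Variable("x"), RDF.type, ns_kegg.Drug)
    ) == {kegg}
    assert worked_fed.truth(
        TriplePattern(Variable("e"), bio2rdf.synonym, Variable("n"))
    ) == {kegg, chebi}
    # ASK {?keggDrug rdf:type kegg:Drug} true only on the KEGG endpoint
    ask = "ASK { ?keggDrug <%s> <%s> }" % (RDF.type.value, ns_kegg.Drug.value)
    for did, name in worked_fed.names.items():
        url = worked_fed.catalogue.endpoint_for(did)
        assert worked_fed.registry.resolve(url).ask(ask) == (name == "kegg")


def test_load_topology_yaml(tmp_path):
    path = tmp_path / "topology.yaml"
    path.write_text(
        """
n_datasets: 3
dataset_names: [drugbank, kegg, chebi]
instances_per_class: 6
seed: 77
cross_links:
  - [drugbank, kegg, keggCompoundId]
literal_overlaps:
  - [[chebi, title], [drugbank, genericName]]
"""
    )
    cfg = load_topology(str(path))
    assert cfg.n_datasets == 3 and cfg.seed == 77
    fed = generate(cfg)
    assert len(fed.graphs) == 3
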