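"""Exclusive grouping and SERVICE/UNION rewriting."""

import random

import pytest

from sparqlfed import (
    IRI,
    exclusive_groups,
    execute,
    parse_query,
    rewrite,
    select_sources,
    solution_multiset,
)
from sparqlfed.algebra import ServiceNode, UnionNode, walk_nodes
from sparqlfed.eval import evaluate_query
from sparqlfed.rewriter import RewriteError
from sparqlfed.selection import RelevanceSets
from sparqlfed.synthetic import synthesize_queries


def test_worked_example_groups(worked_fed, worked_query):
    rel, _ = select_sources(worked_query, worked_fed.catalogue, worked_fed.asker())
    (bgp,) = worked_query.bgps
    groups = exclusive_groups(bgp, rel)
    by_ds = {worked_fed.names[g.dataset_id]: [tp.ordinal for tp in g.patterns] for g in groups}
    assert by_ds == {"drugbank": [0, 1], "kegg": [2, 3]}
    grouped = {tp.ordinal for g in groups for tp in g.patterns}
    assert 4 not in grouped  # the synonym pattern is non-exclusive


def test_all_multi_relevant_yields_no_groups(worked_query):
    (bgp,) = worked_query.bgps
    rel = RelevanceSets({tp.key: {IRI("http://a"), IRI("http://b")} for tp in bgp})
    assert exclusive_groups(bgp, rel) == []


def test_groups_equal_brute_force_partition():
    rng = random.Random(31)
    datasets = [IRI(f"http://fed.example/dataset/d{i}") for i in range(6)]
    q = parse_query(
        "SELECT * WHERE { " + " ".join(f"?s <http://p{i}> ?o{i} ." for i in range(8)) + " }"
    )
    (bgp,) = q.bgps
    for _ in range(50):
        rel = RelevanceSets(
            {tp.key: set(rng.sample(datasets, rng.randint(0, 3))) for tp in bgp}
        )
        groups = exclusive_groups(bgp, rel)
        expected = {}
        for tp in bgp:
            if len(rel.per_pattern[tp.key]) == 1:
                (d,) = rel.per_pattern[tp.key]
                expected.setdefault(d, []).append(tp)
        assert {g.dataset_id: list(g.patterns) for g in groups} == expected
        # disjoint and exactly the singleton-relevance patterns
        members = [tp for g in groups for tp in g.patterns]
        assert len(members) == len(set(tp.key for tp in members))
        assert {tp.key for tp in members} == {
            tp.key for tp in bgp if len(rel.per_pattern[tp.key]) == 1
        }


def _service_blocks(rq):
    """Top-level exclusive SERVICE nodes and UNION groups of SERVICE nodes."""
    exclusive, unions = [], []
    for node in walk_nodes(rq.query.root):
        if isinstance(node, UnionNode):
            unions.append(node)
    union_services = {
        id(n) for u in unions for b in u.branches for n in walk_nodes(b) if isinstance(n, ServiceNode)
    }
    for node in walk_nodes(rq.query.root):
        if isinstance(node, ServiceNode) and id(node) not in union_services:
            exclusive.append(node)
    return exclusive, unions


def test_worked_example_rewrite_shape(worked_fed, worked_query):
    rel, _ = select_sources(worked_query, worked_fed.catalogue, worked_fed.asker())
    rq = rewrite(worked_query, rel, worked_fed.catalogue)
    exclusive, unions = _service_blocks(rq)
    assert len(exclusive) == 2
    assert len(unions) == 1 and len(unions[0].branches) == 2
    # the rewritten text is standards-shaped SPARQL 1.1 that re-parses
    q2 = parse_query(rq.text)
    assert "SERVICE" in q2.clauses() and "UNION" in q2.clauses()
    # pattern conservation: same multiset of triple patterns inside blocks
    original = sorted(str(tp) for tp in worked_query.triple_patterns())
    rewritten = sorted(str(tp) for tp in rq.block_patterns())
    assert original == rewritten


def test_single_pattern_single_source_is_one_service(worked_fed):
    q = parse_query(
        "SELECT * WHERE { ?d <http://bio2rdf.example/ns/drugbank#keggCompoundId> ?c . }"
    )
    rel, _ = select_sources(q, worked_fed.catalogue, worked_fed.asker())
    rq = rewrite(q, rel, worked_fed.catalogue)
    services = [n for n in walk_nodes(rq.query.root) if isinstance(n, ServiceNode)]
    assert len(services) == 1
    assert services[0].endpoint.value == "http://drugbank.example/sparql"


def test_empty_relevance_block_and_strict_mode(worked_fed):
    q = parse_query("SELECT * WHERE { ?s <http://nowhere.example/p> ?o . }")
    rel, _ = select_sources(q, worked_fed.catalogue, worked_fed.asker())
    rq = rewrite(q, rel, worked_fed.catalogue)
    assert rq.warnings
    sols, _ = execute(rq, worked_fed.registry)
    assert sols == []
    with pytest.raises(RewriteError):
        rewrite(q, rel, worked_fed.catalogue, strict=True)


def test_grouping_off_same_results_more_blocks(worked_fed, worked_query):
    rel, _ = select_sources(worked_query, worked_fed.catalogue, worked_fed.asker())
    grouped = rewrite(worked_query, rel, worked_fed.catalogue)
    ungrouped = rewrite(worked_query, rel, worked_fed.catalogue, group=False)
    n_grouped = sum(1 for n in walk_nodes(grouped.query.root) if isinstance(n, ServiceNode))
    n_ungrouped = sum(1 for n in walk_nodes(ungrouped.query.root) if isinstance(n, ServiceNode))
    assert n_ungrouped > n_grouped
    a, _ = execute(grouped, worked_fed.registry)
    b, _ = execute(ungrouped, worked_fed.registry)
    assert solution_multiset(a) == solution_multiset(b)


def test_filter_pushed_into_covering_service(worked_fed):
    q = parse_query(
        """SELECT * WHERE {
          ?d <http://bio2rdf.example/ns/drugbank#genericName> ?g .
          FILTER REGEX(?g, "generic")
        }"""
    )
    rel, _ = select_sources(q, worked_fed.catalogue, worked_fed.asker())
    rq = rewrite(q, rel, worked_fed.catalogue)
    # the filter lives inside the SERVICE block, not above it
    service = next(n for n in walk_nodes(rq.query.root) if isinstance(n, ServiceNode))
    from sparqlfed.algebra import FilterNode

    assert any(isinstance(n, FilterNode) for n in walk_nodes(service.child))
    sols, _ = execute(rq, worked_fed.registry)
    ref = evaluate_query(q, graph=worked_fed.merged_graph())
    assert solution_multiset(sols) == solution_multiset(ref)


def test_rewrite_execute_equals_merged_graph(small_fed):
    merged = small_fed.merged_graph()
    asker = small_fed.asker()
    for text in synthesize_queries(small_fed, 24, seed=17):
        q = parse_query(text)
        rel, _ = select_sources(q, small_fed.catalogue, asker)
        rq = rewrite(q, rel, small_fed.catalogue)
        sols, _ = execute(rq, small_fed.registry)
        ref = evaluate_query(q, graph=merged)
        assert solution_multiset(sols) == solution_multiset(ref), text
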