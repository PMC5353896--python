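"""Two-step source selection: worked example, oracle equivalence, accounting."""

import pytest

from sparqlfed import (
    FederationAsker,
    IRI,
    index_free_ask_count,
    parse_query,
    select_sources,
    ttpwss,
)
from sparqlfed.selection import SelectionError
from sparqlfed.synthetic import synthesize_queries
from sparqlfed.terms import bound
from sparqlfed.workload import BENCHMARK_WORKLOAD


def test_worked_example_selection(worked_fed, worked_query):
    rel, rep = select_sources(worked_query, worked_fed.catalogue, worked_fed.asker())
    assert rel.sizes() == [1, 1, 1, 1, 2]
    assert ttpwss(rel) == 6
    assert rep.ttpwss == 6
    # pattern 1: DrugBank only, object bound -> 1 ASK; pattern 3: rdf:type in
    # all 10 datasets, object bound -> 10 ASKs pruned down to KEGG
    assert rep.per_pattern_before[(0, 0)] == 1
    assert rep.per_pattern_before[(0, 2)] == 10
    assert rep.ask_requests == 11
    assert len(rep.per_pattern_pruned[(0, 2)]) == 9
    kegg = worked_fed.dataset("kegg")
    chebi = worked_fed.dataset("chebi")
    assert rel.per_pattern[(0, 2)] == {kegg}
    assert rel.per_pattern[(0, 4)] == {kegg, chebi}


def test_unbound_everything_selects_all_without_asks(worked_fed):
    q = parse_query("SELECT * WHERE { ?s ?p ?o }")
    rel, rep = select_sources(q, worked_fed.catalogue, worked_fed.asker())
    assert rel.per_pattern[(0, 0)] == set(worked_fed.dataset_ids)
    assert rep.ask_requests == 0


def test_selection_equals_truth_oracle_on_seeded_queries(small_fed):
    """Final relevance sets equal brute-force per-graph pattern evaluation."""
    asker = small_fed.asker()
    for text in synthesize_queries(small_fed, 40, seed=5):
        q = parse_query(text)
        rel, rep = select_sources(q, small_fed.catalogue, asker)
        for tp in q.triple_patterns():
            # bound s/o: ASK pruning gives exact relevance; otherwise the
            # index answer (predicate presence) is already exact for these
            # queries, since every synthesized predicate is bound
            assert rel.per_pattern[tp.key] == small_fed.truth(tp)


def test_pruning_is_sound_and_monotone(small_fed):
    asker = small_fed.asker()
    for text in synthesize_queries(small_fed, 20, seed=9):
        q = parse_query(text)
        pruned_rel, pruned_rep = select_sources(q, small_fed.catalogue, asker)
        index_rel, index_rep = select_sources(q, small_fed.catalogue, asker, prune=False)
        assert index_rep.ask_requests == 0
        assert ttpwss(pruned_rel) <= ttpwss(index_rel)
        for key, removed in pruned_rep.per_pattern_pruned.items():
            tp = next(t for t in q.triple_patterns() if t.key == key)
            for did in removed:
                assert did not in small_fed.truth(tp)  # removed source had no match


def test_ask_request_accounting_formula(small_fed):
    asker = small_fed.asker()
    for text in synthesize_queries(small_fed, 20, seed=13):
        q = parse_query(text)
        rel, rep = select_sources(q, small_fed.catalogue, asker)
        eligible = sum(
            rep.per_pattern_before[tp.key]
            for tp in q.triple_patterns()
            if bound(tp.subject) or bound(tp.object)
        )
        assert rep.ask_requests == eligible


def test_index_free_baseline_counting(worked_query):
    q4 = parse_query(
        "SELECT * WHERE { ?a <http://p1> ?b . ?b <http://p2> ?c . "
        "?c <http://p3> ?d . ?d <http://p4> ?e . }"
    )
    assert index_free_ask_count(q4, 10) == 40
    assert index_free_ask_count(parse_query("SELECT * WHERE { }"), 10) == 0
    assert index_free_ask_count(worked_query, 10) == 50
    # across the published 20-query workload: 10 datasets x 139 patterns
    assert 10 * sum(s.tp_count for s in BENCHMARK_WORKLOAD) == 1390


def test_availability_prefilter_excludes_down_dataset(worked_fed, worked_query):
    live = set(worked_fed.dataset_ids) - {worked_fed.dataset("chebi")}
    rel, rep = select_sources(
        worked_query, worked_fed.catalogue, worked_fed.asker(), live_datasets=live
    )
    assert rel.sizes() == [1, 1, 1, 1, 1]  # pattern 5 loses the ChEBI mirror


def test_ask_transport_failure_policies(worked_fed, worked_query):
    from sparqlfed.endpoints import EndpointUnreachable

    class FailingAsker:
        def __init__(self, inner, failing):
            self.inner, self.failing = inner, failing

        def ask(self, dataset_id, pattern):
            if dataset_id == self.failing:
                raise EndpointUnreachable("http://drugbank.example/sparql")
            return self.inner.ask(dataset_id, pattern)

    failing = FailingAsker(worked_fed.asker(), worked_fed.dataset("drugbank"))
    rel, rep = select_sources(worked_query, worked_fed.catalogue, failing)
    assert rel.per_pattern[(0, 0)] == set()  # treated as down, removed
    assert rep.ask_failures
    with pytest.raises(EndpointUnreachable):
        select_sources(worked_query, worked_fed.catalogue, failing, on_ask_error="abort")


def test_warm_cache_suppresses_repeat_asks(worked_fed, worked_query):
    cache = {}
    _, cold = select_sources(worked_query, worked_fed.catalogue, worked_fed.asker(), ask_cache=cache)
    _, warm = select_sources(worked_query, worked_fed.catalogue, worked_fed.asker(), ask_cache=cache)
    assert cold.ask_requests == 11 and warm.ask_requests == 0


def test_empty_catalogue_is_an_error(worked_query):
    from sparqlfed import Catalogue

    with pytest.raises(SelectionError):
        select_sources(worked_query, Catalogue(), asker=None)
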