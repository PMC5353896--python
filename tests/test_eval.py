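"""Evaluator semantics against a brute-force substitution oracle."""

import itertools
import random

from sparqlfed import Graph, IRI, Literal, parse_query
from sparqlfed.eval import evaluate_query, solution_multiset
from sparqlfed.terms import RDF, Variable, XSD


def brute_force_bgp(patterns, graph):
    """Try every assignment of graph terms... by iterating triple tuples per
    pattern and checking binding consistency — independent of the engine's
    incremental matcher."""
    triples = list(graph)
    out = []
    for combo in itertools.product(triples, repeat=len(patterns)):
        binding = {}
        ok = True
        for tp, triple in zip(patterns, combo):
            for term, value in zip(tp.terms(), triple):
                if term.kind in ("variable", "blank"):
                    name = term.lexical if term.kind == "variable" else "_:" + term.lexical
                    if binding.get(name, value) != value:
                        ok = False
                        break
                    binding[name] = value
                elif term != value:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            out.append(binding)
    return out


def small_graph(seed):
    rng = random.Random(seed)
    g = Graph()
    nodes = [IRI(f"http://ex/n{i}") for i in range(5)]
    preds = [IRI(f"http://ex/p{i}") for i in range(3)]
    for _ in range(15):
        g.add(rng.choice(nodes), rng.choice(preds), rng.choice(nodes + [Literal(str(rng.randrange(3)))]))
    return g


def test_bgp_matching_agrees_with_product_oracle():
    rng = random.Random(77)
    for seed in range(8):
        g = small_graph(seed)
        terms = ["?x", "?y", "?z", "<http://ex/n1>", "<http://ex/p0>"]
        patterns_txt = " ".join(
            f"{rng.choice(terms[:4])} {rng.choice(['?p', '<http://ex/p0>', '<http://ex/p1>'])} {rng.choice(terms[:4])} ."
            for _ in range(rng.randint(1, 3))
        )
        q = parse_query("SELECT * WHERE { %s }" % patterns_txt)
        got = evaluate_query(q, graph=g)
        expected = brute_force_bgp(q.triple_patterns(), g)
        proj = q.effective_projection()
        expected_proj = [{k: v for k, v in b.items() if k in proj} for b in expected]
        assert solution_multiset(got) == solution_multiset(expected_proj)


def build_demo_graph():
    g = Graph()
    ex = "http://ex/"
    for i, label in [(1, "alpha"), (2, "beta"), (3, "gamma")]:
        g.add(IRI(f"{ex}i{i}"), RDF.type, IRI(f"{ex}C"))
        g.add(IRI(f"{ex}i{i}"), IRI(f"{ex}label"), Literal(label))
        g.add(IRI(f"{ex}i{i}"), IRI(f"{ex}size"), Literal(str(i * 10), datatype=XSD.integer))
    g.add(IRI(f"{ex}i1"), IRI(f"{ex}extra"), Literal("bonus"))
    return g


def test_optional_is_a_left_join():
    g = build_demo_graph()
    q = parse_query(
        """SELECT * WHERE {
          ?s <http://ex/label> ?l .
          OPTIONAL { ?s <http://ex/extra> ?e . }
        }"""
    )
    sols = evaluate_query(q, graph=g)
    assert len(sols) == 3
    with_extra = [s for s in sols if "e" in s]
    assert len(with_extra) == 1 and with_extra[0]["e"] == Literal("bonus")


def test_union_concatenates_bags():
    g = build_demo_graph()
    q = parse_query(
        """SELECT ?s WHERE {
          { ?s <http://ex/extra> ?v . } UNION { ?s <http://ex/label> ?v . }
        }"""
    )
    assert len(evaluate_query(q, graph=g)) == 4


def test_filter_comparisons_and_regex():
    g = build_demo_graph()
    q = parse_query(
        "SELECT ?s WHERE { ?s <http://ex/size> ?n . FILTER (?n > 10 && ?n <= 30) }"
    )
    assert len(evaluate_query(q, graph=g)) == 2
    q = parse_query(
        'SELECT ?s WHERE { ?s <http://ex/label> ?l . FILTER REGEX(?l, "^A", "i") }'
    )
    assert len(evaluate_query(q, graph=g)) == 1
    # errors (unbound var in filter) eliminate the solution rather than raising
    q = parse_query("SELECT ?s WHERE { ?s <http://ex/label> ?l . FILTER (?missing = 1) }")
    assert evaluate_query(q, graph=g) == []


def test_numeric_comparison_is_not_lexicographic():
    g = Graph()
    g.add(IRI("http://ex/a"), IRI("http://ex/size"), Literal("9", datatype=XSD.integer))
    g.add(IRI("http://ex/b"), IRI("http://ex/size"), Literal("10", datatype=XSD.integer))
    q = parse_query("SELECT ?s WHERE { ?s <http://ex/size> ?n . FILTER (?n < 10) }")
    sols = evaluate_query(q, graph=g)
    assert [s["s"].value for s in sols] == ["http://ex/a"]  # "9" < "10" numerically


def test_filter_bound_over_optional():
    g = build_demo_graph()
    q = parse_query(
        """SELECT ?s WHERE {
          ?s <http://ex/label> ?l .
          OPTIONAL { ?s <http://ex/extra> ?e . }
          FILTER (! BOUND(?e))
        }"""
    )
    assert len(evaluate_query(q, graph=g)) == 2


def test_distinct_order_limit():
    g = build_demo_graph()
    q = parse_query("SELECT DISTINCT ?c WHERE { ?s a ?c . }")
    assert len(evaluate_query(q, graph=g)) == 1
    q = parse_query(
        "SELECT ?l WHERE { ?s <http://ex/label> ?l . } ORDER BY DESC(?l) LIMIT 2"
    )
    sols = evaluate_query(q, graph=g)
    assert [s["l"].lexical for s in sols] == ["gamma", "beta"]


def test_ask_via_graph_endpoint():
    from sparqlfed import GraphEndpoint

    ep = GraphEndpoint(build_demo_graph())
    assert ep.ask("ASK { ?s <http://ex/extra> ?o }") is True
    assert ep.ask("ASK { ?s <http://ex/absent> ?o }") is False
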