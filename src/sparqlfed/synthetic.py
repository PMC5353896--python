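"""Seeded synthetic multi-endpoint life-science federation.

Emulates the topology of the classic drug/pathway/compound federations used to
benchmark SPARQL endpoint federation: ten datasets in the style of DrugBank,
KEGG, ChEBI, SIDER, Diseasome and friends, each with its own classes and
exclusive predicates, federation-wide common predicates (``rdf:type``,
``rdfs:label``) in every dataset, cross-dataset object links (a drug pointing
at a pathway-database compound), and shared-literal overlaps (a "title"
predicate in one dataset carrying the same literal values as another dataset's
"genericName").  Scale is deliberately small — hundreds of triples per dataset,
not the millions of the real deployments — which is enough for non-trivial
joins while keeping every test sub-second.

The generator returns the graphs, a catalogue built by actually probing each
graph endpoint (so catalogue and ground truth cannot drift apart), a populated
endpoint registry with a mirror URL per dataset, and a ``truth`` function that
answers per-pattern relevance by direct per-graph evaluation — the oracle side
of every selection and equivalence test.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

from .algebra import TriplePattern
from .catalogue import Catalogue, probe_endpoint
from .endpoints import EndpointRegistry, GraphEndpoint
from .eval import _match_bgp
from .graph import Graph
from .selection import FederationAsker
from .terms import IRI, Literal, Namespace, RDF, RDFS, Term, Variable

__all__ = [
    "TopologyConfig",
    "SyntheticFederation",
    "generate",
    "worked_example_fixture",
    "WORKED_EXAMPLE_QUERY",
    "synthesize_queries",
    "load_topology",
]

DEFAULT_DATASET_NAMES = (
    "drugbank",
    "kegg",
    "chebi",
    "sider",
    "diseasome",
    "dailymed",
    "linkedct",
    "medicare",
    "affymetrix",
    "tcga",
)

# drug-centred connectivity: drugs link out to pathway compounds, side effects,
# disorders, trial interventions; expression probes link to the genome atlas
DEFAULT_CROSS_LINKS = (
    ("drugbank", "kegg", "keggCompoundId"),
    ("drugbank", "sider", "sideEffect"),
    ("drugbank", "diseasome", "possibleDiseaseTarget"),
    ("dailymed", "drugbank", "genericDrug"),
    ("linkedct", "drugbank", "intervention"),
    ("tcga", "affymetrix", "expressionProbe"),
)

# distinct predicates in different datasets sharing literal values
DEFAULT_LITERAL_OVERLAPS = (
    (("chebi", "title"), ("drugbank", "genericName")),
    (("tcga", "drug_name"), ("drugbank", "genericName")),
)


@dataclass(frozen=True)
class TopologyConfig:
    """Declarative description of a synthetic federation."""

    n_datasets: int = 10
    dataset_names: Tuple[str, ...] = DEFAULT_DATASET_NAMES
    exclusive_predicates_per_dataset: int = 3
    shared_predicates: Tuple[str, ...] = ("type", "label")  # rdf:type, rdfs:label
    cross_links: Tuple[Tuple[str, str, str], ...] = DEFAULT_CROSS_LINKS
    literal_overlaps: Tuple[Tuple[Tuple[str, str], Tuple[str, str]], ...] = (
        DEFAULT_LITERAL_OVERLAPS
    )
    instances_per_class: int = 30
    mirrors_per_dataset: int = 1
    seed: int = 42

    def names(self) -> Tuple[str, ...]:
        if self.n_datasets <= len(self.dataset_names):
            return self.dataset_names[: self.n_datasets]
        extra = tuple(f"ds{i}" for i in range(len(self.dataset_names), self.n_datasets))
        return self.dataset_names + extra

    def active_cross_links(self) -> Tuple[Tuple[str, str, str], ...]:
        """Cross links among the active datasets.  Built-in default links whose
        endpoints were truncated away by a small ``n_datasets`` are silently
        dropped; an explicitly configured link naming an unknown dataset is an
        error."""
        known = set(self.names())
        out = []
        for link in self.cross_links:
            if link[0] in known and link[1] in known:
                out.append(link)
            elif link not in DEFAULT_CROSS_LINKS:
                missing = link[0] if link[0] not in known else link[1]
                raise ValueError(f"cross link names unknown dataset {missing!r}")
        return tuple(out)

    def active_literal_overlaps(self):
        known = set(self.names())
        out = []
        for overlap in self.literal_overlaps:
            (a, _), (b, _) = overlap
            if a in known and b in known:
                out.append(overlap)
            elif overlap not in DEFAULT_LITERAL_OVERLAPS:
                missing = a if a not in known else b
                raise ValueError(f"literal overlap names unknown dataset {missing!r}")
        return tuple(out)

    def validate(self) -> None:
        if self.n_datasets < 1:
            raise ValueError("a federation needs at least one dataset")
        self.active_cross_links()
        self.active_literal_overlaps()


def load_topology(path: str) -> TopologyConfig:
    """Read a topology config from a YAML file (keys mirror the dataclass)."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}

    def tup(value, depth=1):
        if value is None:
            return None
        return tuple(tup(v, depth - 1) if depth > 1 else (tuple(v) if isinstance(v, list) else v) for v in value)

    kwargs = {}
    for key in (
        "n_datasets",
        "exclusive_predicates_per_dataset",
        "instances_per_class",
        "mirrors_per_dataset",
        "seed",
    ):
        if key in raw:
            kwargs[key] = int(raw[key])
    if "dataset_names" in raw:
        kwargs["dataset_names"] = tuple(raw["dataset_names"])
    if "shared_predicates" in raw:
        kwargs["shared_predicates"] = tuple(raw["shared_predicates"])
    if "cross_links" in raw:
        kwargs["cross_links"] = tuple(tuple(link) for link in raw["cross_links"])
    if "literal_overlaps" in raw:
        kwargs["literal_overlaps"] = tuple(
            (tuple(a), tuple(b)) for a, b in raw["literal_overlaps"]
        )
    config = TopologyConfig(**kwargs)
    config.validate()
    return config


# ---------------------------------------------------------------------------
# IRI scheme (bio2rdf style: vocabularies under ns/<name>#, instances as
# <base>/<name>:<local>)

_BASE = "http://bio2rdf.example"


def vocab_ns(name: str) -> Namespace:
    return Namespace(f"{_BASE}/ns/{name}#")


def common_ns() -> Namespace:
    return Namespace(f"{_BASE}/ns/bio2rdf#")


def instance_iri(name: str, local: str) -> IRI:
    return IRI(f"{_BASE}/{name}:{local}")


def dataset_iri(name: str) -> IRI:
    return IRI(f"http://fed.example/dataset/{name}")


def endpoint_urls(name: str, mirrors: int) -> List[str]:
    urls = [f"http://{name}.example/sparql"]
    urls.extend(f"http://mirror{m}.{name}.example/sparql" for m in range(1, mirrors + 1))
    return urls


@dataclass
class SyntheticFederation:
    config: Optional[TopologyConfig]
    graphs: Dict[IRI, Graph]
    names: Dict[IRI, str]
    catalogue: Catalogue
    registry: EndpointRegistry

    @property
    def dataset_ids(self) -> List[IRI]:
        return list(self.graphs)

    def dataset(self, name: str) -> IRI:
        for did, n in self.names.items():
            if n == name:
                return did
        raise KeyError(name)

    def merged_graph(self) -> Graph:
        return Graph.merged(self.graphs.values())

    def asker(self) -> FederationAsker:
        return FederationAsker(self.catalogue, self.registry)

    def truth(self, tp: TriplePattern) -> Set[IRI]:
        """Ground-truth relevance: datasets whose graph matches the pattern."""
        return {
            did for did, g in self.graphs.items() if _match_bgp([tp], g, {})
        }

    def remove_dataset(self, dataset_id: IRI) -> None:
        """Drop a dataset everywhere (graphs, catalogue, registry, truth)."""
        descriptor = self.catalogue.descriptors.pop(dataset_id, None)
        self.graphs.pop(dataset_id, None)
        self.names.pop(dataset_id, None)
        if descriptor:
            for url in descriptor.endpoint_urls:
                self.registry.deregister(url)


def _register(fed_graphs: Dict[IRI, Graph], names: Dict[IRI, str], mirrors: int) -> tuple[Catalogue, EndpointRegistry]:
    registry = EndpointRegistry()
    catalogue = Catalogue()
    for did, graph in fed_graphs.items():
        name = names[did]
        urls = endpoint_urls(name, mirrors)
        primary = GraphEndpoint(graph, url=urls[0])
        registry.register(urls[0], primary)
        for mirror_url in urls[1:]:
            registry.register(mirror_url, GraphEndpoint(graph, url=mirror_url))
        catalogue.add(probe_endpoint(primary, did, endpoint_urls=urls, title=name))
    return catalogue, registry


def generate(config: Optional[TopologyConfig] = None) -> SyntheticFederation:
    """Build a deterministic synthetic federation from a topology config."""
    config = config or TopologyConfig()
    config.validate()
    rng = random.Random(config.seed)
    names = config.names()
    bio2rdf = common_ns()

    graphs: Dict[IRI, Graph] = {}
    id_of: Dict[IRI, str] = {}
    instances: Dict[str, List[IRI]] = {}

    # pass 1: instances, classes, labels, exclusive predicates
    for name in names:
        ns = vocab_ns(name)
        g = Graph()
        cls = ns[name.capitalize() + "Entity"]
        members = [instance_iri(name, str(i)) for i in range(config.instances_per_class)]
        instances[name] = members
        for i, inst in enumerate(members):
            if "type" in config.shared_predicates:
                g.add(inst, RDF.type, cls)
            if "label" in config.shared_predicates:
                g.add(inst, RDFS.label, Literal(f"{name} entity {i}"))
        for k in range(config.exclusive_predicates_per_dataset):
            pred = ns[f"x{k}"]
            for i, inst in enumerate(members):
                if rng.random() < 0.7:
                    if k % 2 == 0:
                        g.add(inst, pred, Literal(f"{name}-v{k}-{rng.randrange(10)}"))
                    else:
                        g.add(inst, pred, members[rng.randrange(len(members))])
        graphs[dataset_iri(name)] = g
        id_of[dataset_iri(name)] = name

    # pass 2: cross-dataset object links
    for src, tgt, local in config.active_cross_links():
        g = graphs[dataset_iri(src)]
        pred = vocab_ns(src)[local]
        for inst in instances[src]:
            if rng.random() < 0.5:
                g.add(inst, pred, instances[tgt][rng.randrange(len(instances[tgt]))])

    # pass 3: shared-literal overlaps
    for oi, ((name_a, local_a), (name_b, local_b)) in enumerate(config.active_literal_overlaps()):
        pool = [Literal(f"shared-{oi}-{v}") for v in range(10)]
        for name, local in ((name_a, local_a), (name_b, local_b)):
            g = graphs[dataset_iri(name)]
            pred = vocab_ns(name)[local]
            for inst in instances[name]:
                if rng.random() < 0.5:
                    g.add(inst, pred, pool[rng.randrange(len(pool))])

    catalogue, registry = _register(graphs, id_of, config.mirrors_per_dataset)
    return SyntheticFederation(
        config=config, graphs=graphs, names=id_of, catalogue=catalogue, registry=registry
    )


# ---------------------------------------------------------------------------
# The worked five-pattern drug query and its ten-dataset fixture

_DRUGBANK = vocab_ns("drugbank")
_KEGG = vocab_ns("kegg")
_CHEBI = vocab_ns("chebi")
_BIO2RDF = common_ns()

WORKED_EXAMPLE_QUERY = f"""\
PREFIX drugbank: <{_DRUGBANK.base}>
PREFIX drug-category: <{_BASE}/drug-category:>
PREFIX kegg: <{_KEGG.base}>
PREFIX bio2rdf: <{_BIO2RDF.base}>
PREFIX rdf: <{RDF.base}>
SELECT ?drug ?enzyme ?name WHERE {{
  ?drug drugbank:drugCategory drug-category:micronutrient .
  ?drug drugbank:keggCompoundId ?keggDrug .
  ?keggDrug rdf:type kegg:Drug .
  ?keggDrug kegg:xEnzyme ?enzyme .
  ?enzyme bio2rdf:synonym ?name .
}}
"""


def worked_example_fixture(mirrors_per_dataset: int = 1) -> SyntheticFederation:
    """Ten-dataset fixture realizing the worked drug-query relevance profile.

    By construction: ``drugbank:drugCategory`` (with a micronutrient object)
    and ``drugbank:keggCompoundId`` occur only in the DrugBank graph;
    ``kegg:Drug`` instances and ``kegg:xEnzyme`` only in the KEGG graph;
    ``bio2rdf:synonym`` in both KEGG and ChEBI; ``rdf:type`` in all ten
    graphs.  The merged graph yields at least one solution for
    :data:`WORKED_EXAMPLE_QUERY`, so selection sizes are (1, 1, 1, 1, 2).
    """
    names = DEFAULT_DATASET_NAMES
    graphs: Dict[IRI, Graph] = {}
    id_of: Dict[IRI, str] = {}

    micronutrient = IRI(f"{_BASE}/drug-category:micronutrient")
    vitamin = IRI(f"{_BASE}/drug-category:vitamin")

    db = Graph()
    for i in range(1, 6):
        drug = instance_iri("drugbank", f"DB{i:05d}")
        db.add(drug, RDF.type, _DRUGBANK.Drug)
        db.add(drug, RDFS.label, Literal(f"drug {i}"))
        db.add(drug, _DRUGBANK.drugCategory, micronutrient if i <= 2 else vitamin)
        db.add(drug, _DRUGBANK.keggCompoundId, instance_iri("kegg", f"C{i:05d}"))
        db.add(drug, _DRUGBANK.genericName, Literal(f"generic-{i}"))

    kg = Graph()
    for i in range(1, 6):
        compound = instance_iri("kegg", f"C{i:05d}")
        enzyme = instance_iri("ec", f"3.2.1.{i}")
        kg.add(compound, RDF.type, _KEGG.Drug)
        kg.add(compound, RDFS.label, Literal(f"kegg compound {i}"))
        kg.add(compound, _KEGG.xEnzyme, enzyme)
        kg.add(enzyme, RDF.type, _KEGG.Enzyme)
        kg.add(enzyme, _BIO2RDF.synonym, Literal(f"hydrolase-{i}"))

    ch = Graph()
    for i in range(1, 6):
        compound = instance_iri("chebi", f"{17000 + i}")
        ch.add(compound, RDF.type, _CHEBI.Compound)
        ch.add(compound, RDFS.label, Literal(f"chebi compound {i}"))
        ch.add(compound, _CHEBI.title, Literal(f"generic-{i}"))
        ch.add(compound, _BIO2RDF.synonym, Literal(f"chebi-synonym-{i}"))

    graphs[dataset_iri("drugbank")] = db
    graphs[dataset_iri("kegg")] = kg
    graphs[dataset_iri("chebi")] = ch
    for name in names[3:]:
        ns = vocab_ns(name)
        g = Graph()
        for i in range(1, 4):
            inst = instance_iri(name, str(i))
            g.add(inst, RDF.type, ns[name.capitalize() + "Entity"])
            g.add(inst, RDFS.label, Literal(f"{name} entity {i}"))
            g.add(inst, ns.x0, Literal(f"{name}-value-{i}"))
        graphs[dataset_iri(name)] = g
    for name in names:
        id_of[dataset_iri(name)] = name

    catalogue, registry = _register(graphs, id_of, mirrors_per_dataset)
    return SyntheticFederation(
        config=None, graphs=graphs, names=id_of, catalogue=catalogue, registry=registry
    )


# ---------------------------------------------------------------------------
# Seeded query synthesis over the generated vocabulary


def synthesize_queries(
    fed: SyntheticFederation,
    n: int,
    seed: int = 0,
    kinds: Sequence[str] = ("star", "chain", "bound", "union", "filter", "distinct"),
) -> List[str]:
    """Generate ``n`` SELECT queries over the federation's own vocabulary.

    Shapes: subject stars, object-subject chains, patterns with a bound
    subject or object sampled from the data (exercising ASK pruning), UNIONs
    of single-pattern branches, REGEX/inequality filters, and DISTINCT
    variants.  All texts use absolute IRIs and parse with the package parser.
    """
    rng = random.Random(seed)
    all_triples: List[tuple[IRI, Term, Term, Term]] = []
    for did, g in fed.graphs.items():
        for t in g:
            all_triples.append((did, t.subject, t.predicate, t.object))
    predicates = sorted({p.n3() for _, _, p, _ in all_triples})

    def sample_triple():
        return all_triples[rng.randrange(len(all_triples))]

    out: List[str] = []
    for qi in range(n):
        kind = kinds[qi % len(kinds)]
        body: List[str] = []
        if kind == "star":
            _, s, p, o = sample_triple()
            k = rng.choice((2, 3))
            preds = {p.n3()}
            body.append(f"?s {p.n3()} ?o0 .")
            for j in range(1, k):
                _, _, p2, _ = sample_triple()
                if p2.n3() in preds:
                    continue
                preds.add(p2.n3())
                body.append(f"?s {p2.n3()} ?o{j} .")
        elif kind == "chain":
            did, s, p, o = sample_triple()
            body.append(f"?a {p.n3()} ?b .")
            hops = [t for t in all_triples if t[1] == o]
            if hops:
                _, _, p2, _ = hops[rng.randrange(len(hops))]
                body.append(f"?b {p2.n3()} ?c .")
            else:
                _, _, p2, _ = sample_triple()
                body.append(f"?b {p2.n3()} ?c .")
        elif kind == "bound":
            _, s, p, o = sample_triple()
            if rng.random() < 0.5:
                body.append(f"{s.n3()} {p.n3()} ?o .")
            else:
                body.append(f"?s {p.n3()} {o.n3()} .")
            _, _, p2, _ = sample_triple()
            body.append(f"?s2 {p2.n3()} ?o2 ." if rng.random() < 0.5 else f"?s {p2.n3()} ?z .")
        elif kind == "union":
            p1 = predicates[rng.randrange(len(predicates))]
            p2 = predicates[rng.randrange(len(predicates))]
            out.append(
                "SELECT * WHERE { { ?s " + p1 + " ?o . } UNION { ?s " + p2 + " ?o . } }"
            )
            continue
        elif kind == "filter":
            _, s, p, o = sample_triple()
            body.append(f"?s {p.n3()} ?o .")
            if isinstance(o, Literal):
                token = o.lexical.split("-")[0]
                body.append(f'FILTER REGEX(?o, "{token}")')
            else:
                body.append(f"FILTER (?o != {o.n3()})")
        else:  # distinct
            _, s, p, o = sample_triple()
            out.append(f"SELECT DISTINCT ?s WHERE {{ ?s {p.n3()} ?o . }}")
            continue
        out.append("SELECT * WHERE {\n  " + "\n  ".join(body) + "\n}")
    return out
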