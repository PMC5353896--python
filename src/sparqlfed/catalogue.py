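"""Dataset cataloguing: probe endpoints, summarize them, persist as VoID.

The catalogue is the index half of hybrid source selection: for every dataset
it records the distinct classes (with one probed example resource each and a
URI regex pattern generalized from it) and the distinct predicates (with
labels, sampled domain/range classes and an example object), plus the ordered
list of SPARQL endpoint URLs serving the dataset (primary first, mirrors
after).  Inverted predicate and class indexes answer the per-triple-pattern
lookup of the selection algorithm.

Persistence uses the VoID vocabulary in Turtle: one ``void:Dataset`` per
descriptor with multi-valued ``void:sparqlEndpoint``, and class/property
partitions carrying ``void:class``, ``void:exampleResource``,
``void:uriRegexPattern`` and ``void:property``.  Which VoID property attaches
the predicate list is a convention of this package (property partitions); the
vocabulary itself does not mandate one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Union

from .endpoints import Endpoint
from .graph import Graph
from .terms import DCTERMS, IRI, Literal, Namespace, RDF, RDFS, Term, VOID, XSD

__all__ = [
    "ProbeBudget",
    "ClassRecord",
    "PredicateRecord",
    "DatasetDescriptor",
    "Catalogue",
    "CatalogueError",
    "probe_endpoint",
    "derive_uri_pattern",
    "write_catalogue",
    "read_catalogue",
    "catalogue_to_graph",
    "catalogue_from_graph",
]

EXT = Namespace("urn:x-catalogue:")  # partial/built-at flags with no VoID term

_RDF_TYPE_N3 = RDF.type.n3()


class CatalogueError(RuntimeError):
    pass


@dataclass(frozen=True)
class ProbeBudget:
    """Limits for endpoint probing.

    One example resource per class and a 10 000-row page mirror typical public
    endpoint restrictions; 60 s is the customary per-request endpoint timeout.
    """

    examples_per_class: int = 1
    page_size: int = 10_000
    timeout_s: float = 60.0
    sample_domains_ranges: bool = True


@dataclass
class ClassRecord:
    class_iri: IRI
    label: str = ""
    example_resources: List[IRI] = field(default_factory=list)
    uri_regex_pattern: Optional[str] = None


@dataclass
class PredicateRecord:
    predicate_iri: IRI
    label: str = ""
    domain_class: Optional[IRI] = None
    range_class: Optional[IRI] = None
    example_object: Optional[Term] = None


@dataclass
class DatasetDescriptor:
    dataset_id: IRI
    title: str = ""
    endpoint_urls: List[str] = field(default_factory=list)
    classes: List[ClassRecord] = field(default_factory=list)
    predicates: List[PredicateRecord] = field(default_factory=list)
    partial: bool = False
    built_at: Optional[str] = None  # ISO timestamp; staleness is surfaced, not solved

    def predicate_iris(self) -> List[IRI]:
        return [p.predicate_iri for p in self.predicates]

    def class_iris(self) -> List[IRI]:
        return [c.class_iri for c in self.classes]

    def validate(self) -> None:
        if not self.endpoint_urls:
            raise CatalogueError(f"descriptor {self.dataset_id.value} has no endpoint URL")
        preds = self.predicate_iris()
        if len(preds) != len(set(preds)):
            raise CatalogueError(f"duplicate predicate IRIs in {self.dataset_id.value}")
        classes = self.class_iris()
        if len(classes) != len(set(classes)):
            raise CatalogueError(f"duplicate class IRIs in {self.dataset_id.value}")


class Catalogue:
    """Descriptor collection with inverted predicate and class indexes."""

    def __init__(self, descriptors: Optional[Sequence[DatasetDescriptor]] = None) -> None:
        self.descriptors: Dict[IRI, DatasetDescriptor] = {}
        for d in descriptors or []:
            self.add(d)

    def add(self, descriptor: DatasetDescriptor) -> None:
        if descriptor.dataset_id in self.descriptors:
            raise CatalogueError(f"duplicate dataset IRI {descriptor.dataset_id.value}")
        descriptor.validate()
        self.descriptors[descriptor.dataset_id] = descriptor

    @property
    def predicate_index(self) -> Dict[IRI, Set[IRI]]:
        index: Dict[IRI, Set[IRI]] = {}
        for did, d in self.descriptors.items():
            for p in d.predicate_iris():
                index.setdefault(p, set()).add(did)
        return index

    @property
    def class_index(self) -> Dict[IRI, Set[IRI]]:
        index: Dict[IRI, Set[IRI]] = {}
        for did, d in self.descriptors.items():
            for c in d.class_iris():
                index.setdefault(c, set()).add(did)
        return index

    def dataset_ids(self) -> List[IRI]:
        return list(self.descriptors)

    def predicate_lookup(self, predicate: IRI) -> Set[IRI]:
        """Datasets whose descriptor lists the predicate; empty set if unknown."""
        return set(self.predicate_index.get(predicate, set()))

    def class_lookup(self, cls: IRI) -> Set[IRI]:
        return set(self.class_index.get(cls, set()))

    def endpoint_for(self, dataset_id: IRI) -> str:
        """The primary (first-listed) endpoint URL of a dataset."""
        return self.descriptors[dataset_id].endpoint_urls[0]

    def __len__(self) -> int:
        return len(self.descriptors)


# ---------------------------------------------------------------------------
# Probing


def probe_endpoint(
    endpoint: Endpoint,
    dataset_id: IRI,
    endpoint_urls: Optional[Sequence[str]] = None,
    title: Optional[str] = None,
    budget: Optional[ProbeBudget] = None,
    built_at: Optional[str] = None,
) -> DatasetDescriptor:
    """Summarize an endpoint's content into a :class:`DatasetDescriptor`.

    Issues plain SELECT queries (distinct classes, distinct predicates, one
    example resource per class, sampled domain/range per predicate), so it
    works identically against in-process graphs and remote services.  A result
    page hitting the probe page size marks the descriptor ``partial``.
    """
    budget = budget or ProbeBudget()
    limit = budget.page_size
    partial = False

    rows = endpoint.select(f"SELECT DISTINCT ?p WHERE {{ ?s ?p ?o }} LIMIT {limit}")
    partial = partial or len(rows) >= limit
    predicates = [row["p"] for row in rows if isinstance(row.get("p"), IRI)]

    rows = endpoint.select(f"SELECT DISTINCT ?c WHERE {{ ?s {_RDF_TYPE_N3} ?c }} LIMIT {limit}")
    partial = partial or len(rows) >= limit
    classes = [row["c"] for row in rows if isinstance(row.get("c"), IRI)]

    class_records: List[ClassRecord] = []
    for cls in classes:
        examples: List[IRI] = []
        if budget.examples_per_class > 0:
            sols = endpoint.select(
                f"SELECT ?s WHERE {{ ?s {_RDF_TYPE_N3} {cls.n3()} }} LIMIT {budget.examples_per_class}"
            )
            examples = [s["s"] for s in sols if isinstance(s.get("s"), IRI)]
        record = ClassRecord(
            class_iri=cls,
            label=cls.local_name,
            example_resources=examples,
            uri_regex_pattern=derive_uri_pattern(examples[0]) if examples else None,
        )
        class_records.append(record)

    predicate_records: List[PredicateRecord] = []
    for pred in predicates:
        domain = rng = example_obj = None
        if budget.sample_domains_ranges:
            sols = endpoint.select(f"SELECT ?s ?o WHERE {{ ?s {pred.n3()} ?o }} LIMIT 1")
            if sols:
                subj, example_obj = sols[0].get("s"), sols[0].get("o")
                if isinstance(subj, IRI):
                    tsols = endpoint.select(
                        f"SELECT ?t WHERE {{ {subj.n3()} {_RDF_TYPE_N3} ?t }} LIMIT 1"
                    )
                    if tsols and isinstance(tsols[0].get("t"), IRI):
                        domain = tsols[0]["t"]
                # range classes come from rdf:type of sampled objects within the
                # same endpoint; HTTP dereferencing is deliberately not attempted
                if isinstance(example_obj, IRI):
                    tsols = endpoint.select(
                        f"SELECT ?t WHERE {{ {example_obj.n3()} {_RDF_TYPE_N3} ?t }} LIMIT 1"
                    )
                    if tsols and isinstance(tsols[0].get("t"), IRI):
                        rng = tsols[0]["t"]
        predicate_records.append(
            PredicateRecord(
                predicate_iri=pred,
                label=pred.local_name,
                domain_class=domain,
                range_class=rng,
                example_object=example_obj,
            )
        )

    urls = list(endpoint_urls) if endpoint_urls else [getattr(endpoint, "url", "") or dataset_id.value]
    return DatasetDescriptor(
        dataset_id=dataset_id,
        title=title if title is not None else dataset_id.local_name,
        endpoint_urls=urls,
        classes=class_records,
        predicates=predicate_records,
        partial=partial,
        built_at=built_at,
    )


def derive_uri_pattern(example: Union[IRI, str]) -> str:
    """Generalize an example resource IRI into an anchored URI regex.

    The fixed prefix runs up to and including the last ``#``, ``/`` or ``:``
    delimiter of the local identifier (the scheme colon never counts); the
    local identifier itself becomes a wildcard.  An IRI with no local segment
    yields an exact-match pattern.

    >>> derive_uri_pattern("http://bio2rdf.org/ec:3.2.1.161")
    '^http://bio2rdf\\\\.org/ec:[^/#]+$'
    """
    iri = example.value if isinstance(example, IRI) else example
    scheme_end = iri.find("://")
    scheme_end = scheme_end + 3 if scheme_end >= 0 else iri.find(":") + 1
    idx = max(iri.rfind("#"), iri.rfind("/", scheme_end), iri.rfind(":", scheme_end))
    if idx < scheme_end or idx == len(iri) - 1:
        return "^" + re.escape(iri) + "$"
    return "^" + re.escape(iri[: idx + 1]) + "[^/#]+$"


# ---------------------------------------------------------------------------
# VoID persistence

_PREFIXES = {
    "void": VOID.base,
    "rdf": RDF.base,
    "rdfs": RDFS.base,
    "dcterms": DCTERMS.base,
    "xsd": XSD.base,
    "cat": EXT.base,
}


def catalogue_to_graph(catalogue: Catalogue) -> Graph:
    from .terms import BlankNode

    g = Graph()
    for di, descriptor in enumerate(catalogue.descriptors.values()):
        descriptor.validate()
        ds = descriptor.dataset_id
        g.add(ds, RDF.type, VOID.Dataset)
        if descriptor.title:
            g.add(ds, DCTERMS.title, Literal(descriptor.title))
        for url in descriptor.endpoint_urls:
            g.add(ds, VOID.sparqlEndpoint, IRI(url))
        if descriptor.partial:
            g.add(ds, EXT.partial, Literal("true", datatype=XSD.boolean))
        if descriptor.built_at:
            g.add(ds, DCTERMS.modified, Literal(descriptor.built_at, datatype=XSD.dateTime))
        for ci, cls in enumerate(descriptor.classes):
            node = BlankNode(f"d{di}c{ci}")
            g.add(ds, VOID.classPartition, node)
            g.add(node, VOID["class"], cls.class_iri)
            if cls.label:
                g.add(node, RDFS.label, Literal(cls.label))
            for res in cls.example_resources:
                g.add(node, VOID.exampleResource, res)
            if cls.uri_regex_pattern:
                g.add(node, VOID.uriRegexPattern, Literal(cls.uri_regex_pattern))
        for pi, pred in enumerate(descriptor.predicates):
            node = BlankNode(f"d{di}p{pi}")
            g.add(ds, VOID.propertyPartition, node)
            g.add(node, VOID.property, pred.predicate_iri)
            if pred.label:
                g.add(node, RDFS.label, Literal(pred.label))
            if pred.domain_class:
                g.add(node, RDFS.domain, pred.domain_class)
            if pred.range_class:
                g.add(node, RDFS.range, pred.range_class)
            if pred.example_object is not None:
                g.add(node, VOID.exampleResource, pred.example_object)
    return g


def catalogue_from_graph(g: Graph) -> Catalogue:
    catalogue = Catalogue()
    for t in g.match(None, RDF.type, VOID.Dataset):
        ds = t.subject
        if not isinstance(ds, IRI):
            raise CatalogueError("void:Dataset subject must be an IRI")
        titles = [x.object for x in g.match(ds, DCTERMS.title)]
        urls = [x.object.value for x in g.match(ds, VOID.sparqlEndpoint) if isinstance(x.object, IRI)]
        partial = any(
            isinstance(x.object, Literal) and x.object.lexical == "true"
            for x in g.match(ds, EXT.partial)
        )
        built = [x.object.lexical for x in g.match(ds, DCTERMS.modified) if isinstance(x.object, Literal)]

        classes: List[ClassRecord] = []
        for part in (x.object for x in g.match(ds, VOID.classPartition)):
            iris = [x.object for x in g.match(part, VOID["class"]) if isinstance(x.object, IRI)]
            if not iris:
                continue
            labels = [x.object.lexical for x in g.match(part, RDFS.label) if isinstance(x.object, Literal)]
            examples = [x.object for x in g.match(part, VOID.exampleResource) if isinstance(x.object, IRI)]
            patterns = [x.object.lexical for x in g.match(part, VOID.uriRegexPattern) if isinstance(x.object, Literal)]
            classes.append(
                ClassRecord(
                    class_iri=iris[0],
                    label=labels[0] if labels else "",
                    example_resources=examples,
                    uri_regex_pattern=patterns[0] if patterns else None,
                )
            )
        predicates: List[PredicateRecord] = []
        for part in (x.object for x in g.match(ds, VOID.propertyPartition)):
            iris = [x.object for x in g.match(part, VOID.property) if isinstance(x.object, IRI)]
            if not iris:
                continue
            labels = [x.object.lexical for x in g.match(part, RDFS.label) if isinstance(x.object, Literal)]
            domains = [x.object for x in g.match(part, RDFS.domain) if isinstance(x.object, IRI)]
            ranges = [x.object for x in g.match(part, RDFS.range) if isinstance(x.object, IRI)]
            examples = [x.object for x in g.match(part, VOID.exampleResource)]
            predicates.append(
                PredicateRecord(
                    predicate_iri=iris[0],
                    label=labels[0] if labels else "",
                    domain_class=domains[0] if domains else None,
                    range_class=ranges[0] if ranges else None,
                    example_object=examples[0] if examples else None,
                )
            )
        descriptor = DatasetDescriptor(
            dataset_id=ds,
            title=titles[0].lexical if titles and isinstance(titles[0], Literal) else "",
            endpoint_urls=urls,
            classes=classes,
            predicates=predicates,
            partial=partial,
            built_at=built[0] if built else None,
        )
        catalogue.add(descriptor)
    if not catalogue.descriptors:
        raise CatalogueError("document contains no void:Dataset descriptions")
    return catalogue


def write_catalogue(catalogue: Catalogue, sink: str) -> None:
    """Serialize the catalogue as VoID/Turtle to ``sink``."""
    text = catalogue_to_graph(catalogue).to_turtle(prefixes=_PREFIXES)
    with open(sink, "w", encoding="utf-8") as fh:
        fh.write(text)


def read_catalogue(source: str) -> Catalogue:
    """Load a VoID/Turtle catalogue file and rebuild both indexes."""
    with open(source, "r", encoding="utf-8") as fh:
        text = fh.read()
    return catalogue_from_graph(Graph.from_turtle(text))
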