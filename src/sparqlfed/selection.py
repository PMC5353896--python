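"""Hybrid triple-pattern-wise source selection.

Two steps per triple pattern: (1) an index lookup — a bound predicate selects
the datasets whose catalogue descriptor lists it, an unbound predicate selects
every dataset; (2) ASK pruning — when the subject or the object is bound, an
ASK query holding the whole pattern is sent to each candidate, and candidates
answering false are dropped.  The total triple-pattern-wise sources selected
(TTPWSS) is the sum of relevance-set sizes over the query's patterns; the
report also carries the number of ASK requests issued (#AR) and the selection
time (SST), split into index and ASK components.

An index-free engine that knows nothing about the datasets must instead ASK
every dataset about every pattern; ``index_free_ask_count`` reproduces that
baseline (datasets x patterns) for comparison.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Protocol, Set

from .algebra import ParsedQuery, PatternKey, TriplePattern, term_to_sparql
from .catalogue import Catalogue
from .endpoints import EndpointRegistry, EndpointUnreachable
from .terms import IRI, Term, Variable, bound

__all__ = [
    "RelevanceSets",
    "SelectionReport",
    "SelectionError",
    "Asker",
    "FederationAsker",
    "ask_query_text",
    "select_sources",
    "ttpwss",
    "index_free_ask_count",
]


class SelectionError(RuntimeError):
    pass


@dataclass
class RelevanceSets:
    """Per-pattern relevant datasets, keyed by (BGP id, pattern ordinal)."""

    per_pattern: Dict[PatternKey, Set[IRI]] = field(default_factory=dict)

    def for_pattern(self, tp: TriplePattern) -> Set[IRI]:
        return self.per_pattern[tp.key]

    def sizes(self) -> List[int]:
        return [len(s) for s in self.per_pattern.values()]

    def total(self) -> int:
        return sum(self.sizes())


@dataclass
class SelectionReport:
    ttpwss: int = 0
    ask_requests: int = 0
    selection_time_ms: float = 0.0
    index_time_ms: float = 0.0
    ask_time_ms: float = 0.0
    per_pattern_before: Dict[PatternKey, int] = field(default_factory=dict)
    per_pattern_pruned: Dict[PatternKey, Set[IRI]] = field(default_factory=dict)
    ask_failures: List[str] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)


class Asker(Protocol):
    """Per-dataset ASK capability."""

    def ask(self, dataset_id: IRI, pattern: TriplePattern) -> bool: ...


def ask_query_text(pattern: TriplePattern) -> str:
    s = term_to_sparql(pattern.subject)
    p = term_to_sparql(pattern.predicate)
    o = term_to_sparql(pattern.object)
    return f"ASK {{ {s} {p} {o} }}"


class FederationAsker:
    """Routes ASK queries to each dataset's primary endpoint."""

    def __init__(self, catalogue: Catalogue, registry: EndpointRegistry) -> None:
        self.catalogue = catalogue
        self.registry = registry

    def ask(self, dataset_id: IRI, pattern: TriplePattern) -> bool:
        url = self.catalogue.endpoint_for(dataset_id)
        return self.registry.resolve(url).ask(ask_query_text(pattern))


def select_sources(
    q: ParsedQuery,
    catalogue: Catalogue,
    asker: Asker,
    prune: bool = True,
    live_datasets: Optional[Set[IRI]] = None,
    on_ask_error: str = "treat-as-down",
    ask_cache: Optional[Dict] = None,
) -> tuple[RelevanceSets, SelectionReport]:
    """Run the two-step selection over every triple pattern of ``q``.

    Parameters
    ----------
    prune:
        Disable to get index-only selection (relevance sets before ASK).
    live_datasets:
        Pre-selection availability filter: when given, candidates outside this
        set are excluded before any ASK is issued.
    on_ask_error:
        ``"treat-as-down"`` removes a dataset whose ASK transport failed and
        records the event; ``"abort"`` re-raises.
    ask_cache:
        Optional dict reproducing warm-cache behaviour; cache hits do not
        count as issued ASK requests.  Default is cold (no cache).
    """
    if not catalogue.descriptors:
        raise SelectionError("cannot select sources against an empty catalogue")
    if on_ask_error not in ("treat-as-down", "abort"):
        raise ValueError(f"unknown ASK error policy {on_ask_error!r}")

    all_datasets = set(catalogue.dataset_ids())
    relevance = RelevanceSets()
    report = SelectionReport()
    t_start = time.perf_counter()

    patterns = q.triple_patterns()
    for tp in patterns:
        t0 = time.perf_counter()
        if isinstance(tp.predicate, IRI):
            candidates = catalogue.predicate_lookup(tp.predicate)
        else:
            candidates = set(all_datasets)
        if live_datasets is not None:
            candidates &= live_datasets
        report.index_time_ms += (time.perf_counter() - t0) * 1000
        report.per_pattern_before[tp.key] = len(candidates)

        # pruning applies whenever the subject or object is bound, even if the
        # predicate is a variable
        if prune and (bound(tp.subject) or bound(tp.object)) and candidates:
            t0 = time.perf_counter()
            kept: Set[IRI] = set()
            pruned: Set[IRI] = set()
            cache_key_base = ask_query_text(tp)
            for ds in sorted(candidates, key=lambda d: d.value):
                key = (ds, cache_key_base)
                if ask_cache is not None and key in ask_cache:
                    answer = ask_cache[key]
                else:
                    report.ask_requests += 1
                    try:
                        answer = asker.ask(ds, tp)
                    except EndpointUnreachable as exc:
                        if on_ask_error == "abort":
                            raise
                        report.ask_failures.append(f"{ds.value}: {exc}")
                        answer = False
                    if ask_cache is not None:
                        ask_cache[key] = answer
                (kept if answer else pruned).add(ds)
            if pruned:
                report.per_pattern_pruned[tp.key] = pruned
            candidates = kept
            report.ask_time_ms += (time.perf_counter() - t0) * 1000

        if not candidates:
            report.warnings.append(
                f"pattern {tp.key} has an empty relevance set: {ask_query_text(tp)[4:]}"
            )
        relevance.per_pattern[tp.key] = candidates

    report.ttpwss = relevance.total()
    report.selection_time_ms = (time.perf_counter() - t_start) * 1000
    return relevance, report


def ttpwss(relevance: RelevanceSets) -> int:
    """Total triple-pattern-wise sources selected: sum of relevance-set sizes."""
    return relevance.total()


def index_free_ask_count(q: ParsedQuery, n_datasets: int) -> int:
    """ASK requests a cold index-free engine needs: datasets x triple patterns."""
    if n_datasets < 0:
        raise ValueError("n_datasets must be non-negative")
    return n_datasets * q.tp_count
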