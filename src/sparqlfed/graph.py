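"""In-memory RDF graph with pattern matching and Turtle/N-Triples I/O.

The store keeps insertion order (serialization is deterministic and mirror-URL
order survives a round trip) and indexes triples by predicate, which is the
access path everything here cares about: catalogue probing, ASK pruning and BGP
evaluation are all predicate-driven.
"""

from __future__ import annotations

from typing import Dict, Iterable, Iterator, List, Optional, Set, Tuple

from .terms import IRI, BlankNode, Literal, RDF, Term, Triple, Variable

_TripleKey = Tuple[Term, Term, Term]


class Graph:
    """A set of RDF triples in insertion order."""

    def __init__(self, triples: Optional[Iterable[Triple]] = None) -> None:
        self._triples: Dict[_TripleKey, None] = {}
        self._by_predicate: Dict[Term, List[Triple]] = {}
        if triples:
            for t in triples:
                self.add(t)

    # -- mutation -----------------------------------------------------------

    def add(self, triple_or_s, p: Optional[Term] = None, o: Optional[Term] = None) -> None:
        if p is None:
            triple = triple_or_s
        else:
            triple = Triple(triple_or_s, p, o)
        key = (triple.subject, triple.predicate, triple.object)
        if key in self._triples:
            return
        self._triples[key] = None
        self._by_predicate.setdefault(triple.predicate, []).append(triple)

    def update(self, triples: Iterable[Triple]) -> None:
        for t in triples:
            self.add(t)

    # -- access -------------------------------------------------------------

    def __len__(self) -> int:
        return len(self._triples)

    def __iter__(self) -> Iterator[Triple]:
        for s, p, o in self._triples:
            yield Triple(s, p, o)

    def __contains__(self, triple: Triple) -> bool:
        return (triple.subject, triple.predicate, triple.object) in self._triples

    def match(
        self,
        s: Optional[Term] = None,
        p: Optional[Term] = None,
        o: Optional[Term] = None,
    ) -> Iterator[Triple]:
        """Triples matching a template; ``None`` is a wildcard."""
        if p is not None and p in self._by_predicate:
            candidates: Iterable[Triple] = self._by_predicate[p]
        elif p is not None:
            return
        else:
            candidates = iter(self)
        for t in candidates:
            if s is not None and t.subject != s:
                continue
            if o is not None and t.object != o:
                continue
            yield t

    def ask(self, s: Optional[Term] = None, p: Optional[Term] = None, o: Optional[Term] = None) -> bool:
        return next(self.match(s, p, o), None) is not None

    def predicates(self) -> List[Term]:
        """Distinct predicates in first-seen order."""
        return list(self._by_predicate)

    def classes(self) -> List[Term]:
        """Distinct ``rdf:type`` objects in first-seen order."""
        seen: Dict[Term, None] = {}
        for t in self._by_predicate.get(RDF.type, []):
            seen.setdefault(t.object)
        return list(seen)

    def subjects_of_type(self, cls: Term) -> List[Term]:
        return [t.subject for t in self.match(None, RDF.type, cls)]

    # -- combination --------------------------------------------------------

    @classmethod
    def merged(cls, graphs: Iterable["Graph"]) -> "Graph":
        out = cls()
        for g in graphs:
            out.update(g)
        return out

    # -- serialization ------------------------------------------------------

    def to_ntriples(self) -> str:
        lines = [f"{t.subject.n3()} {t.predicate.n3()} {t.object.n3()} ." for t in self]
        return "\n".join(lines) + ("\n" if lines else "")

    def to_turtle(self, prefixes: Optional[Dict[str, str]] = None) -> str:
        prefixes = prefixes or {}
        reverse = sorted(prefixes.items(), key=lambda kv: -len(kv[1]))

        def fmt(term: Term) -> str:
            if isinstance(term, IRI):
                for pfx, base in reverse:
                    local = term.value[len(base):]
                    if term.value.startswith(base) and _safe_local(local):
                        return f"{pfx}:{local}"
                return term.n3()
            if isinstance(term, Literal) and term.datatype is not None:
                return f'"{_esc(term.lexical)}"^^{fmt(term.datatype)}'
            return term.n3()

        out: List[str] = [f"@prefix {pfx}: <{base}> ." for pfx, base in sorted(prefixes.items())]
        if out:
            out.append("")
        # group consecutive triples sharing a subject
        by_subject: Dict[Term, List[Triple]] = {}
        for t in self:
            by_subject.setdefault(t.subject, []).append(t)
        for subj, triples in by_subject.items():
            preds: Dict[Term, List[Term]] = {}
            for t in triples:
                preds.setdefault(t.predicate, []).append(t.object)
            lines: List[str] = []
            for p, objects in preds.items():
                pred_txt = "a" if p == RDF.type else fmt(p)
                lines.append(f"    {pred_txt} {', '.join(fmt(o) for o in objects)}")
            out.append(f"{fmt(subj)}\n" + " ;\n".join(lines) + " .")
        return "\n".join(out) + ("\n" if out else "")

    @classmethod
    def from_turtle(cls, text: str) -> "Graph":
        from .turtle import parse_turtle

        return parse_turtle(text)

    @classmethod
    def from_ntriples(cls, text: str) -> "Graph":
        from .turtle import parse_turtle

        return parse_turtle(text)  # N-Triples is a Turtle subset


def _esc(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"').replace("\n", "\\n")


def _safe_local(local: str) -> bool:
    if local == "":
        return False
    if local[0] == "." or local[-1] == ".":
        return False
    return all(c.isalnum() or c in "_.-" for c in local)
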