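"""RDF terms and triples.

The four term kinds of the RDF abstract syntax — IRIs, literals, blank nodes —
plus SPARQL query variables.  A triple pattern position is *bound* when it holds
an IRI or a literal; variables and blank nodes are unbound (blank nodes in a
query act as scoped variables under SPARQL semantics).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Union

__all__ = [
    "IRI",
    "Literal",
    "BlankNode",
    "Variable",
    "Term",
    "Triple",
    "bound",
    "Namespace",
    "RDF",
    "RDFS",
    "XSD",
    "VOID",
    "DCTERMS",
]


@dataclass(frozen=True, slots=True)
class IRI:
    """An absolute IRI reference."""

    value: str

    kind = "iri"

    @property
    def lexical(self) -> str:
        return self.value

    @property
    def local_name(self) -> str:
        """Substring after the last of '#', ':' or '/' (label heuristic)."""
        idx = max(self.value.rfind(c) for c in "#:/")
        return self.value[idx + 1 :]

    def n3(self) -> str:
        return f"<{self.value}>"

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.n3()


_STRING_ESCAPES = {"\\": "\\\\", '"': '\\"', "\n": "\\n", "\r": "\\r", "\t": "\\t"}


def _escape(s: str) -> str:
    return "".join(_STRING_ESCAPES.get(c, c) for c in s)


@dataclass(frozen=True, slots=True)
class Literal:
    """An RDF literal with optional datatype IRI or language tag."""

    lexical: str
    datatype: Optional[IRI] = None
    language: Optional[str] = None

    kind = "literal"

    def __post_init__(self) -> None:
        if self.datatype is not None and self.language is not None:
            raise ValueError("a literal cannot carry both a datatype and a language tag")

    def n3(self) -> str:
        out = f'"{_escape(self.lexical)}"'
        if self.language:
            out += f"@{self.language}"
        elif self.datatype is not None:
            out += f"^^{self.datatype.n3()}"
        return out

    @property
    def value(self) -> Union[str, int, float, bool]:
        """Python value for filter evaluation; falls back to the lexical form."""
        if self.datatype is not None:
            dt = self.datatype.value
            try:
                if dt in _INTEGER_TYPES:
                    return int(self.lexical)
                if dt in _DECIMAL_TYPES:
                    return float(self.lexical)
                if dt == XSD.boolean.value:
                    return self.lexical in ("true", "1")
            except ValueError:
                return self.lexical
        return self.lexical

    def __str__(self) -> str:  # pragma: no cover
        return self.n3()


@dataclass(frozen=True, slots=True)
class BlankNode:
    label: str

    kind = "blank"

    @property
    def lexical(self) -> str:
        return self.label

    def n3(self) -> str:
        return f"_:{self.label}"

    def __str__(self) -> str:  # pragma: no cover
        return self.n3()


@dataclass(frozen=True, slots=True)
class Variable:
    """A SPARQL variable; ``name`` excludes the leading '?' / '$'."""

    name: str

    kind = "variable"

    def __post_init__(self) -> None:
        if not self.name or self.name[0] in "?$":
            raise ValueError(f"bad variable name: {self.name!r}")

    @property
    def lexical(self) -> str:
        return self.name

    def n3(self) -> str:
        return f"?{self.name}"

    def __str__(self) -> str:  # pragma: no cover
        return self.n3()


Term = Union[IRI, Literal, BlankNode, Variable]


def bound(term: Term) -> bool:
    """True iff the term is a constant (IRI or literal)."""
    return isinstance(term, (IRI, Literal))


@dataclass(frozen=True, slots=True)
class Triple:
    subject: Term
    predicate: Term
    object: Term

    def __iter__(self):
        yield self.subject
        yield self.predicate
        yield self.object


class Namespace:
    """Attribute-style IRI minting: ``VOID.sparqlEndpoint``."""

    def __init__(self, base: str) -> None:
        self._base = base

    def __getattr__(self, local: str) -> IRI:
        if local.startswith("_"):
            raise AttributeError(local)
        return IRI(self._base + local)

    def __getitem__(self, local: str) -> IRI:
        return IRI(self._base + local)

    def term(self, local: str) -> IRI:
        return IRI(self._base + local)

    @property
    def base(self) -> str:
        return self._base


RDF = Namespace("http://www.w3.org/1999/02/22-rdf-syntax-ns#")
RDFS = Namespace("http://www.w3.org/2000/01/rdf-schema#")
XSD = Namespace("http://www.w3.org/2001/XMLSchema#")
VOID = Namespace("http://rdfs.org/ns/void#")
DCTERMS = Namespace("http://purl.org/dc/terms/")

_INTEGER_TYPES = frozenset(
    XSD[t].value
    for t in (
        "integer",
        "int",
        "long",
        "short",
        "byte",
        "nonNegativeInteger",
        "positiveInteger",
        "negativeInteger",
        "nonPositiveInteger",
        "unsignedInt",
        "unsignedLong",
    )
)
_DECIMAL_TYPES = frozenset(XSD[t].value for t in ("decimal", "float", "double"))

_ABS_IRI = re.compile(r"^[A-Za-z][A-Za-z0-9+.-]*:")


def is_absolute_iri(s: str) -> bool:
    return _ABS_IRI.match(s) is not None
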