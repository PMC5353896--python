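"""Turtle reader for the subset this package emits and consumes.

Supported: ``@prefix``/``@base`` (and SPARQL-style ``PREFIX``/``BASE``),
prefixed names, IRIs, labelled blank nodes, the ``a`` keyword, predicate lists
(``;``), object lists (``,``), plain/typed/language-tagged string literals,
numeric literals and booleans.  Collections and ``[...]`` anonymous property
lists are not emitted by this package and are rejected with a parse error.
"""

from __future__ import annotations

from typing import Dict

from .graph import Graph
from .lexer import TokenError, TokenStream, tokenize
from .terms import IRI, XSD, BlankNode, Literal, RDF, Term, is_absolute_iri

__all__ = ["parse_turtle", "TurtleParseError"]


class TurtleParseError(SyntaxError):
    pass


def parse_turtle(text: str) -> Graph:
    try:
        return _Parser(text).parse()
    except TokenError as exc:
        raise TurtleParseError(str(exc)) from exc


class _Parser:
    def __init__(self, text: str) -> None:
        self.ts = TokenStream(tokenize(text))
        self.prefixes: Dict[str, str] = {}
        self.base = ""
        self.graph = Graph()

    def parse(self) -> Graph:
        ts = self.ts
        while ts.current.type != "eof":
            if ts.current.type == "langtag" and ts.current.value in ("prefix", "base"):
                directive = ts.advance().value
                self._directive(directive, terminated=True)
            elif ts.at_keyword("PREFIX"):
                ts.advance()
                self._directive("prefix", terminated=False)
            elif ts.at_keyword("BASE"):
                ts.advance()
                self._directive("base", terminated=False)
            else:
                self._triples()
                ts.expect_op(".")
        return self.graph

    def _directive(self, which: str, terminated: bool) -> None:
        ts = self.ts
        if which == "prefix":
            tok = ts.current
            if tok.type != "pname" or tok.extra:
                raise ts.error("expected prefix declaration like 'ex:'")
            ts.advance()
            iri = ts.current
            if iri.type != "iri":
                raise ts.error("expected IRI in prefix declaration")
            ts.advance()
            self.prefixes[tok.value] = self._resolve(iri.value)
        else:
            iri = ts.current
            if iri.type != "iri":
                raise ts.error("expected IRI in base declaration")
            ts.advance()
            self.base = self._resolve(iri.value)
        if terminated:
            ts.expect_op(".")

    def _resolve(self, iri: str) -> str:
        if is_absolute_iri(iri) or not self.base:
            return iri
        return self.base + iri

    def _triples(self) -> None:
        subject = self._term(position="subject")
        self._predicate_object_list(subject)

    def _predicate_object_list(self, subject: Term) -> None:
        ts = self.ts
        while True:
            predicate = self._verb()
            while True:
                obj = self._term(position="object")
                self.graph.add(subject, predicate, obj)
                if ts.at_op(","):
                    ts.advance()
                    continue
                break
            if ts.at_op(";"):
                ts.advance()
                if ts.at_op(".") or ts.at_op(";"):
                    continue  # stray ';' before '.'
                if ts.current.type == "eof":
                    break
                continue
            break

    def _verb(self) -> Term:
        ts = self.ts
        if ts.current.type == "ident" and ts.current.value == "a":
            ts.advance()
            return RDF.type
        return self._term(position="predicate")

    def _term(self, position: str) -> Term:
        ts = self.ts
        tok = ts.current
        if tok.type == "iri":
            ts.advance()
            return IRI(self._resolve(tok.value))
        if tok.type == "pname":
            ts.advance()
            if tok.value not in self.prefixes:
                raise TokenError(f"undeclared prefix {tok.value!r}", tok.line, tok.col)
            return IRI(self.prefixes[tok.value] + (tok.extra or ""))
        if tok.type == "bnode":
            ts.advance()
            return BlankNode(tok.value)
        if position != "object" and tok.type in ("string", "number"):
            raise ts.error(f"literal not allowed in {position} position")
        if tok.type == "string":
            ts.advance()
            if ts.current.type == "langtag":
                return Literal(tok.value, language=ts.advance().value)
            if ts.at_op("^^"):
                ts.advance()
                dt = self._term(position="datatype")
                if not isinstance(dt, IRI):
                    raise ts.error("datatype must be an IRI")
                return Literal(tok.value, datatype=dt)
            return Literal(tok.value)
        if tok.type == "number":
            ts.advance()
            if any(c in tok.value for c in ".eE"):
                dt = XSD.double if ("e" in tok.value or "E" in tok.value) else XSD.decimal
            else:
                dt = XSD.integer
            return Literal(tok.value, datatype=dt)
        if tok.type == "ident" and tok.value in ("true", "false"):
            ts.advance()
            return Literal(tok.value, datatype=XSD.boolean)
        raise ts.error(f"unexpected token {tok.value!r} in {position} position")
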