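"""Solution-sequence writers: text, CSV, TSV, JSON, Turtle and XML.

CSV/TSV follow the W3C SPARQL 1.1 results conventions (plain lexical forms in
CSV, N-Triples-style terms in TSV); JSON and XML follow the standard results
formats; Turtle uses the RDF result-set vocabulary.  The text format is a
human-readable aligned table.
"""

from __future__ import annotations

import csv
import io
import json
from typing import Dict, List, Optional, Sequence
from xml.etree import ElementTree as ET

from .eval import Solution
from .graph import Graph
from .terms import IRI, BlankNode, Literal, Namespace, RDF, Term, XSD

__all__ = ["write_results", "FORMATS"]

RS = Namespace("http://www.w3.org/2001/sw/DataAccess/tests/result-set#")

FORMATS = ("txt", "csv", "tsv", "json", "ttl", "xml")


def _variables(solutions: Sequence[Solution], variables: Optional[Sequence[str]]) -> List[str]:
    if variables is not None:
        return list(variables)
    seen: Dict[str, None] = {}
    for sol in solutions:
        for v in sol:
            seen.setdefault(v)
    return list(seen)


def write_results(
    solutions: Sequence[Solution],
    fmt: str,
    variables: Optional[Sequence[str]] = None,
) -> str:
    """Serialize bindings to one of the six supported download formats."""
    if fmt not in FORMATS:
        raise ValueError(f"unknown result format {fmt!r}; expected one of {FORMATS}")
    header = _variables(solutions, variables)
    writer = {
        "txt": _write_txt,
        "csv": _write_csv,
        "tsv": _write_tsv,
        "json": _write_json,
        "ttl": _write_ttl,
        "xml": _write_xml,
    }[fmt]
    return writer(solutions, header)


def _plain(term: Optional[Term]) -> str:
    if term is None:
        return ""
    if isinstance(term, Literal):
        return term.lexical
    if isinstance(term, IRI):
        return term.value
    return "_:" + term.label


def _n3(term: Optional[Term]) -> str:
    return "" if term is None else term.n3()


def _write_txt(solutions: Sequence[Solution], header: List[str]) -> str:
    rows = [[_n3(sol.get(v)) for v in header] for sol in solutions]
    widths = [
        max([len("?" + v)] + [len(r[i]) for r in rows]) for i, v in enumerate(header)
    ] if header else []
    lines = [" | ".join(("?" + v).ljust(w) for v, w in zip(header, widths))]
    lines.append("-+-".join("-" * w for w in widths))
    for r in rows:
        lines.append(" | ".join(c.ljust(w) for c, w in zip(r, widths)))
    return "\n".join(lines) + "\n"


def _write_csv(solutions: Sequence[Solution], header: List[str]) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\r\n")
    w.writerow(header)
    for sol in solutions:
        w.writerow([_plain(sol.get(v)) for v in header])
    return buf.getvalue()


def _write_tsv(solutions: Sequence[Solution], header: List[str]) -> str:
    lines = ["\t".join("?" + v for v in header)]
    for sol in solutions:
        lines.append("\t".join(_n3(sol.get(v)) for v in header))
    return "\n".join(lines) + "\n"


def _json_cell(term: Term) -> dict:
    if isinstance(term, IRI):
        return {"type": "uri", "value": term.value}
    if isinstance(term, BlankNode):
        return {"type": "bnode", "value": term.label}
    cell: dict = {"type": "literal", "value": term.lexical}
    if term.language:
        cell["xml:lang"] = term.language
    elif term.datatype is not None:
        cell["datatype"] = term.datatype.value
    return cell


def _write_json(solutions: Sequence[Solution], header: List[str]) -> str:
    doc = {
        "head": {"vars": header},
        "results": {
            "bindings": [
                {v: _json_cell(sol[v]) for v in header if v in sol} for sol in solutions
            ]
        },
    }
    return json.dumps(doc, indent=2) + "\n"


def _write_ttl(solutions: Sequence[Solution], header: List[str]) -> str:
    g = Graph()
    root = BlankNode("resultSet")
    g.add(root, RDF.type, RS.ResultSet)
    for v in header:
        g.add(root, RS.resultVariable, Literal(v))
    for i, sol in enumerate(solutions):
        snode = BlankNode(f"solution{i}")
        g.add(root, RS.solution, snode)
        for v in header:
            if v not in sol:
                continue
            bnode = BlankNode(f"binding{i}_{v}")
            g.add(snode, RS.binding, bnode)
            g.add(bnode, RS.variable, Literal(v))
            g.add(bnode, RS.value, sol[v])
    return g.to_turtle(prefixes={"rs": RS.base, "rdf": RDF.base, "xsd": XSD.base})


def _write_xml(solutions: Sequence[Solution], header: List[str]) -> str:
    ns = "http://www.w3.org/2005/sparql-results#"
    ET.register_namespace("", ns)
    root = ET.Element(f"{{{ns}}}sparql")
    head = ET.SubElement(root, f"{{{ns}}}head")
    for v in header:
        ET.SubElement(head, f"{{{ns}}}variable", name=v)
    results = ET.SubElement(root, f"{{{ns}}}results")
    for sol in solutions:
        result = ET.SubElement(results, f"{{{ns}}}result")
        for v in header:
            if v not in sol:
                continue
            binding = ET.SubElement(result, f"{{{ns}}}binding", name=v)
            term = sol[v]
            if isinstance(term, IRI):
                ET.SubElement(binding, f"{{{ns}}}uri").text = term.value
            elif isinstance(term, BlankNode):
                ET.SubElement(binding, f"{{{ns}}}bnode").text = term.label
            else:
                lit = ET.SubElement(binding, f"{{{ns}}}literal")
                lit.text = term.lexical
                if term.language:
                    lit.set("xml:lang", term.language)
                elif term.datatype is not None:
                    lit.set("datatype", term.datatype.value)
    return ET.tostring(root, encoding="unicode", xml_declaration=True) + "\n"
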