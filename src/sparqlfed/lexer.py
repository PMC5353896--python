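"""Shared tokenizer for the Turtle and SPARQL readers.

Both grammars draw on the same terminal productions (IRIREF, prefixed names,
string literals, numeric literals, variables, blank-node labels), so a single
tokenizer serves both parsers.  Tokens carry line/column for error reporting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, List, Optional


class TokenError(SyntaxError):
    """Lexical error carrying a 1-based line and column."""

    def __init__(self, message: str, line: int, col: int) -> None:
        super().__init__(f"{message} (line {line}, column {col})")
        self.line = line
        self.col = col


@dataclass(frozen=True, slots=True)
class Token:
    type: str  # iri | pname | var | bnode | string | langtag | number | ident | op | eof
    value: str
    line: int
    col: int
    extra: Optional[str] = None  # pname local part / numeric subtype

    def __repr__(self) -> str:  # pragma: no cover
        return f"Token({self.type}, {self.value!r}, {self.line}:{self.col})"


_IRIREF = re.compile(r'<[^<>"{}|^`\\\x00-\x20]*>')
_VAR = re.compile(r"[?$]([A-Za-z_][A-Za-z0-9_]*)")
_BNODE = re.compile(r"_:([A-Za-z0-9_][A-Za-z0-9_.-]*)")
_STRING_LONG = re.compile(r'"""(?:[^"\\]|\\.|"(?!""))*"""|\'\'\'(?:[^\'\\]|\\.|\'(?!\'\'))*\'\'\'', re.S)
_STRING = re.compile(r'"(?:[^"\\\n]|\\.)*"|\'(?:[^\'\\\n]|\\.)*\'')
_LANGTAG = re.compile(r"@[A-Za-z]+(?:-[A-Za-z0-9]+)*")
_NUMBER = re.compile(r"[+-]?(?:\d+\.\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?|\d+(?:[eE][+-]?\d+)?)")
# Prefixed name: optional prefix part, ':', optional local part (local may start
# with a digit and contain dots, but not end with one).
_PNAME = re.compile(r"(?:[A-Za-z_][A-Za-z0-9_.-]*)?:(?:[A-Za-z0-9_](?:[A-Za-z0-9_.-]*[A-Za-z0-9_-])?)?")
_IDENT = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_OPERATORS = ("^^", "&&", "||", "!=", "<=", ">=", "=", "!", "(", ")", "{", "}", "[", "]", ",", ";", ".", "*", "/", "+", "-", "<", ">")

_UNESCAPE = {
    "\\n": "\n",
    "\\r": "\r",
    "\\t": "\t",
    "\\b": "\b",
    "\\f": "\f",
    '\\"': '"',
    "\\'": "'",
    "\\\\": "\\",
}
_ESCAPE_RE = re.compile(r"\\u[0-9a-fA-F]{4}|\\U[0-9a-fA-F]{8}|\\.")


def _unescape_string(body: str, line: int, col: int) -> str:
    def sub(m: "re.Match[str]") -> str:
        esc = m.group(0)
        if esc.startswith("\\u") or esc.startswith("\\U"):
            return chr(int(esc[2:], 16))
        try:
            return _UNESCAPE[esc]
        except KeyError:
            raise TokenError(f"bad string escape {esc!r}", line, col) from None

    return _ESCAPE_RE.sub(sub, body)


def tokenize(text: str) -> List[Token]:
    """Tokenize Turtle/SPARQL source; appends a sentinel ``eof`` token."""
    tokens: List[Token] = []
    i, n = 0, len(text)
    line, line_start = 1, 0

    def pos() -> tuple[int, int]:
        return line, i - line_start + 1

    while i < n:
        c = text[i]
        if c == "\n":
            line += 1
            i += 1
            line_start = i
            continue
        if c in " \t\r":
            i += 1
            continue
        if c == "#":
            while i < n and text[i] != "\n":
                i += 1
            continue
        ln, col = pos()
        if c == "<":
            m = _IRIREF.match(text, i)
            if m:
                tokens.append(Token("iri", m.group(0)[1:-1], ln, col))
                i = m.end()
                continue
        if c in "\"'":
            m = _STRING_LONG.match(text, i) or _STRING.match(text, i)
            if not m:
                raise TokenError("unterminated string literal", ln, col)
            raw = m.group(0)
            body = raw[3:-3] if raw[:3] in ('"""', "'''") else raw[1:-1]
            tokens.append(Token("string", _unescape_string(body, ln, col), ln, col))
            newlines = raw.count("\n")
            if newlines:
                line += newlines
                line_start = i + raw.rfind("\n") + 1
            i = m.end()
            continue
        if c in "?$":
            m = _VAR.match(text, i)
            if m:
                tokens.append(Token("var", m.group(1), ln, col))
                i = m.end()
                continue
        if c == "_" and text.startswith("_:", i):
            m = _BNODE.match(text, i)
            if m:
                label = m.group(1).rstrip(".")
                tokens.append(Token("bnode", label, ln, col))
                i = i + 2 + len(label)
                continue
        if c == "@":
            m = _LANGTAG.match(text, i)
            if m:
                tokens.append(Token("langtag", m.group(0)[1:], ln, col))
                i = m.end()
                continue
        if c.isdigit() or (c in "+-." and i + 1 < n and text[i + 1].isdigit()):
            m = _NUMBER.match(text, i)
            if m:
                tokens.append(Token("number", m.group(0), ln, col))
                i = m.end()
                continue
        m = _PNAME.match(text, i)
        if m and ":" in m.group(0):
            full = m.group(0)
            prefix, _, local = full.partition(":")
            # PN_LOCAL must not end with '.'; give trailing dots back as terminators
            while local.endswith("."):
                local = local[:-1]
            tokens.append(Token("pname", prefix, ln, col, extra=local))
            i += len(prefix) + 1 + len(local)
            continue
        m = _IDENT.match(text, i)
        if m:
            tokens.append(Token("ident", m.group(0), ln, col))
            i = m.end()
            continue
        for op in _OPERATORS:
            if text.startswith(op, i):
                tokens.append(Token("op", op, ln, col))
                i += len(op)
                break
        else:
            raise TokenError(f"unexpected character {c!r}", ln, col)
    tokens.append(Token("eof", "", line, (n - line_start) + 1))
    return tokens


class TokenStream:
    """Cursor over a token list with small lookahead helpers."""

    def __init__(self, tokens: List[Token]) -> None:
        self._tokens = tokens
        self._i = 0

    @property
    def current(self) -> Token:
        return self._tokens[self._i]

    def peek(self, ahead: int = 1) -> Token:
        j = min(self._i + ahead, len(self._tokens) - 1)
        return self._tokens[j]

    def advance(self) -> Token:
        tok = self._tokens[self._i]
        if tok.type != "eof":
            self._i += 1
        return tok

    def at_op(self, *ops: str) -> bool:
        t = self.current
        return t.type == "op" and t.value in ops

    def at_keyword(self, *words: str) -> bool:
        t = self.current
        return t.type == "ident" and t.value.upper() in words

    def take_keyword(self, *words: str) -> bool:
        if self.at_keyword(*words):
            self.advance()
            return True
        return False

    def expect_op(self, op: str) -> Token:
        t = self.current
        if not self.at_op(op):
            raise TokenError(f"expected {op!r}, found {t.value!r}", t.line, t.col)
        return self.advance()

    def expect_keyword(self, word: str) -> Token:
        t = self.current
        if not self.at_keyword(word):
            raise TokenError(f"expected {word}, found {t.value!r}", t.line, t.col)
        return self.advance()

    def error(self, message: str) -> TokenError:
        t = self.current
        return TokenError(message, t.line, t.col)
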