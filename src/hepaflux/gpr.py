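"""Boolean gene-protein-reaction (GPR) rule parsing and evaluation.

GPR rules associate reactions with genes: subunits of a multimeric enzyme
are combined with AND, isoenzymes with OR, and parentheses group arbitrarily
(e.g. ``(g1 AND g2) OR g3``). Operators are case-insensitive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import FrozenSet, Iterable, Set

__all__ = ["GPRParseError", "GPRRule", "parse_gpr"]


class GPRParseError(ValueError):
    """Raised for a malformed GPR expression; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_TOKEN = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.\-:]+)")


def _tokenize(text: str):
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise GPRParseError(f"unexpected character {text[pos]!r}", pos)
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


@dataclass(frozen=True)
class _Node:
    op: str  # "gene" | "and" | "or"
    name: str = ""
    children: tuple = ()

    def evaluate(self, active: Set[str]) -> bool:
        if self.op == "gene":
            return self.name in active
        if self.op == "and":
            return all(c.evaluate(active) for c in self.children)
        return any(c.evaluate(active) for c in self.children)

    def genes(self) -> Set[str]:
        if self.op == "gene":
            return {self.name}
        out: Set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out


class _Parser:
    # Grammar: expr := term (OR term)* ; term := factor (AND factor)* ;
    #          factor := GENE | "(" expr ")"
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def _peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, len(self.text))

    def _next(self):
        tok = self._peek()
        self.i += 1
        return tok

    def parse(self) -> _Node:
        node = self._expr()
        tok, pos = self._peek()
        if tok is not None:
            raise GPRParseError(f"unexpected token {tok!r}", pos)
        return node

    def _expr(self) -> _Node:
        children = [self._term()]
        while True:
            tok, _ = self._peek()
            if tok is not None and tok.lower() == "or":
                self._next()
                children.append(self._term())
            else:
                break
        return children[0] if len(children) == 1 else _Node("or", children=tuple(children))

    def _term(self) -> _Node:
        children = [self._factor()]
        while True:
            tok, _ = self._peek()
            if tok is not None and tok.lower() == "and":
                self._next()
                children.append(self._factor())
            else:
                break
        return children[0] if len(children) == 1 else _Node("and", children=tuple(children))

    def _factor(self) -> _Node:
        tok, pos = self._next()
        if tok is None:
            raise GPRParseError("unexpected end of expression", pos)
        if tok == "(":
            node = self._expr()
            tok2, pos2 = self._next()
            if tok2 != ")":
                raise GPRParseError("expected ')'", pos2)
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"unexpected token {tok!r}", pos)
        return _Node("gene", name=tok)


@dataclass(frozen=True)
class GPRRule:
    """A parsed GPR rule.

    An empty rule (``text == ""``) means the reaction has no gene
    association (e.g. spontaneous or gap-filled) and always evaluates True.
    """

    text: str
    _root: _Node | None = None

    @property
    def genes(self) -> FrozenSet[str]:
        return frozenset() if self._root is None else frozenset(self._root.genes())

    def evaluate(self, knocked_out: Iterable[str] = ()) -> bool:
        """Evaluate with the listed genes set False and all others True."""
        if self._root is None:
            return True
        active = self.genes - set(knocked_out)
        return self._root.evaluate(active)


def parse_gpr(text: str) -> GPRRule:
    """Parse a Boolean GPR string; raises :class:`GPRParseError` on syntax errors."""
    text = (text or "").strip()
    if not text:
        return GPRRule("")
    return GPRRule(text, _Parser(text).parse())
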