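"""Gene-protein-reaction (GPR) rules: parsing and ternary/boolean evaluation.

A GPR is a boolean expression over gene identifiers, e.g. ``"(g1 and g2) or g3"``,
stating which gene products can catalyse a reaction (AND = enzyme complex,
OR = isozymes).  Besides the usual boolean reading used for in-silico knockouts,
reconstruction needs a *ternary* reading over expression calls
{+1 present, -1 absent, 0 unmeasured}: AND maps to ``min`` and OR to ``max``,
so a complex is only as available as its least-expressed subunit while a single
expressed isozyme suffices.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping


class GPRParseError(ValueError):
    """Raised when a GPR string cannot be parsed."""


@dataclass(frozen=True)
class Gene:
    name: str


@dataclass(frozen=True)
class And:
    children: tuple


@dataclass(frozen=True)
class Or:
    children: tuple


GPRExpr = Gene | And | Or

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")
_KEYWORDS_AND = {"and", "&", "&&"}
_KEYWORDS_OR = {"or", "|", "||"}


def _tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text)


class _Parser:
    """Recursive descent over:  expr := term (OR term)* ; term := atom (AND atom)*."""

    def __init__(self, tokens: list[str], source: str):
        self.tokens = tokens
        self.pos = 0
        self.source = source

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of GPR expression: {self.source!r}")
        self.pos += 1
        return tok

    def parse_expr(self) -> GPRExpr:
        terms = [self.parse_term()]
        while self.peek() is not None and self.peek().lower() in _KEYWORDS_OR:
            self.next()
            terms.append(self.parse_term())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_term(self) -> GPRExpr:
        atoms = [self.parse_atom()]
        while self.peek() is not None and self.peek().lower() in _KEYWORDS_AND:
            self.next()
            atoms.append(self.parse_atom())
        return atoms[0] if len(atoms) == 1 else And(tuple(atoms))

    def parse_atom(self) -> GPRExpr:
        tok = self.next()
        if tok == "(":
            inner = self.parse_expr()
            closing = self.next()
            if closing != ")":
                raise GPRParseError(f"expected ')', got {closing!r} in {self.source!r}")
            return inner
        if tok == ")" or tok.lower() in _KEYWORDS_AND | _KEYWORDS_OR:
            raise GPRParseError(f"unexpected token {tok!r} in {self.source!r}")
        return Gene(tok)


def parse_gpr(text: str) -> GPRExpr | None:
    """Parse a GPR string into an expression tree; empty/blank -> None (no GPR)."""
    if text is None:
        return None
    tokens = _tokenize(text)
    if not tokens:
        return None
    parser = _Parser(tokens, text)
    expr = parser.parse_expr()
    if parser.peek() is not None:
        raise GPRParseError(f"trailing token {parser.peek()!r} in {text!r}")
    return expr


def gpr_genes(expr: GPRExpr | None) -> frozenset[str]:
    if expr is None:
        return frozenset()
    return frozenset(_iter_genes(expr))


def _iter_genes(expr: GPRExpr) -> Iterator[str]:
    if isinstance(expr, Gene):
        yield expr.name
    else:
        for child in expr.children:
            yield from _iter_genes(child)


def eval_ternary(expr: GPRExpr, calls: Mapping[str, int]) -> int:
    """Evaluate a GPR over present/absent calls, returning +1, 0 or -1.

    Genes missing from `calls` (no probe coverage) evaluate to 0 so that an
    unmeasured gene never forces a reaction into the lowly-expressed class.
    """
    if isinstance(expr, Gene):
        return int(calls.get(expr.name, 0))
    if isinstance(expr, And):
        return min(eval_ternary(c, calls) for c in expr.children)
    if isinstance(expr, Or):
        return max(eval_ternary(c, calls) for c in expr.children)
    raise TypeError(f"not a GPR expression: {expr!r}")


def eval_boolean(expr: GPRExpr, knocked_out: frozenset[str] | set[str]) -> bool:
    """Boolean GPR value with the listed genes deleted and all others functional."""
    if isinstance(expr, Gene):
        return expr.name not in knocked_out
    if isinstance(expr, And):
        return all(eval_boolean(c, knocked_out) for c in expr.children)
    if isinstance(expr, Or):
        return any(eval_boolean(c, knocked_out) for c in expr.children)
    raise TypeError(f"not a GPR expression: {expr!r}")


def gpr_to_string(expr: GPRExpr | None) -> str:
    if expr is None:
        return ""
    if isinstance(expr, Gene):
        return expr.name
    op = " and " if isinstance(expr, And) else " or "
    parts = []
    for child in expr.children:
        s = gpr_to_string(child)
        if not isinstance(child, Gene):
            s = f"({s})"
        parts.append(s)
    return op.join(parts)
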