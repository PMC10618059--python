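"""Boolean expression trees and the rule-expression grammar.

Expressions are immutable trees over :class:`Var`, :class:`Const`,
:class:`Not`, :class:`And` and :class:`Or`.  The concrete syntax accepts
the keywords ``AND``/``OR``/``NOT`` (case-insensitive) as well as the
symbols ``&``, ``|``, ``!`` and ``~``, with the usual precedence
``NOT > AND > OR`` and parentheses for grouping.  ``TRUE``/``FALSE``
(also ``1``/``0``) denote constants, so those strings are not available
as variable names.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping


class ExpressionError(ValueError):
    """Raised for malformed or ill-typed Boolean expressions."""


class Expr:
    """Base class of all expression nodes."""

    __slots__ = ()

    def __and__(self, other: "Expr") -> "Expr":
        return And((self, other))

    def __or__(self, other: "Expr") -> "Expr":
        return Or((self, other))

    def __invert__(self) -> "Expr":
        return Not(self)

    def __str__(self) -> str:
        return to_string(self)


@dataclass(frozen=True)
class Var(Expr):
    name: str


@dataclass(frozen=True)
class Const(Expr):
    value: int


@dataclass(frozen=True)
class Not(Expr):
    operand: Expr


@dataclass(frozen=True)
class And(Expr):
    args: tuple


@dataclass(frozen=True)
class Or(Expr):
    args: tuple


def evaluate(expr: Expr, env: Mapping[str, int]) -> int:
    """Evaluate ``expr`` under a variable assignment, returning 0 or 1."""
    if isinstance(expr, Var):
        try:
            return int(env[expr.name])
        except KeyError:
            raise ExpressionError(f"unbound variable {expr.name!r}") from None
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Not):
        return 1 - evaluate(expr.operand, env)
    if isinstance(expr, And):
        return int(all(evaluate(a, env) for a in expr.args))
    if isinstance(expr, Or):
        return int(any(evaluate(a, env) for a in expr.args))
    raise TypeError(f"not an expression: {expr!r}")


def variables(expr: Expr) -> list[str]:
    """Variable names in first-appearance (left-to-right, depth-first) order."""
    seen: list[str] = []

    def walk(e: Expr) -> None:
        if isinstance(e, Var):
            if e.name not in seen:
                seen.append(e.name)
        elif isinstance(e, Not):
            walk(e.operand)
        elif isinstance(e, (And, Or)):
            for a in e.args:
                walk(a)

    walk(expr)
    return seen


_PREC = {Or: 1, And: 2, Not: 3}


def to_string(expr: Expr, _parent_prec: int = 0) -> str:
    """Render an expression with AND/OR/NOT keywords and minimal parentheses."""
    if isinstance(expr, Var):
        return expr.name
    if isinstance(expr, Const):
        return "TRUE" if expr.value else "FALSE"
    if isinstance(expr, Not):
        s = f"NOT {to_string(expr.operand, _PREC[Not])}"
        prec = _PREC[Not]
    elif isinstance(expr, And):
        s = " AND ".join(to_string(a, _PREC[And]) for a in expr.args)
        prec = _PREC[And]
    elif isinstance(expr, Or):
        s = " OR ".join(to_string(a, _PREC[Or]) for a in expr.args)
        prec = _PREC[Or]
    else:
        raise TypeError(f"not an expression: {expr!r}")
    return f"({s})" if prec < _parent_prec else s


# --------------------------------------------------------------------------
# Parsing

_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<lpar>\()
      | (?P<rpar>\))
      | (?P<amp>&)
      | (?P<pipe>\|)
      | (?P<bang>[!~])
      | (?P<name>[A-Za-z0-9_.]+)
    )""",
    re.VERBOSE,
)

_KEYWORDS = {
    "and": "AND",
    "or": "OR",
    "not": "NOT",
    "true": "TRUE",
    "false": "FALSE",
    "1": "TRUE",
    "0": "FALSE",
}


def _tokenize(text: str) -> Iterator[tuple[str, str, int]]:
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise ExpressionError(
                f"unexpected character {stripped[0]!r} at column {pos + 1}"
            )
        pos = m.end()
        kind = m.lastgroup
        tok = m.group(kind)
        if kind == "name":
            kw = _KEYWORDS.get(tok.lower())
            if kw is not None:
                yield kw, tok, m.start(kind)
                continue
        mapping = {"lpar": "(", "rpar": ")", "amp": "AND", "pipe": "OR", "bang": "NOT"}
        yield mapping.get(kind, kind.upper()), tok, m.start(kind)


class _Parser:
    def __init__(self, text: str) -> None:
        self.tokens = list(_tokenize(text))
        self.pos = 0
        self.text = text

    def peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def pop(self) -> tuple[str, str, int]:
        if self.pos >= len(self.tokens):
            raise ExpressionError(f"unexpected end of expression in {self.text!r}")
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self) -> Expr:
        e = self.expr()
        if self.pos != len(self.tokens):
            _, text, col = self.tokens[self.pos]
            raise ExpressionError(f"trailing input {text!r} at column {col + 1}")
        return e

    def expr(self) -> Expr:
        terms = [self.term()]
        while self.peek() == "OR":
            self.pop()
            terms.append(self.term())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def term(self) -> Expr:
        factors = [self.factor()]
        while self.peek() == "AND":
            self.pop()
            factors.append(self.factor())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def factor(self) -> Expr:
        kind, text, col = self.pop()
        if kind == "NOT":
            return Not(self.factor())
        if kind == "(":
            e = self.expr()
            kind, text, col = self.pop()
            if kind != ")":
                raise ExpressionError(f"expected ')' at column {col + 1}, got {text!r}")
            return e
        if kind == "TRUE":
            return Const(1)
        if kind == "FALSE":
            return Const(0)
        if kind == "NAME":
            return Var(text)
        raise ExpressionError(f"unexpected token {text!r} at column {col + 1}")


def parse_expression(text: str) -> Expr:
    """Parse the rule-expression grammar into an :class:`Expr` tree."""
    if not text.strip():
        raise ExpressionError("empty expression")
    return _Parser(text).parse()
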