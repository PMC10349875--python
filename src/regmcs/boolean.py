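"""Boolean expression trees for GPR and regulatory rules.

Gene-protein-reaction (GPR) rules are negation-free Boolean expressions over
gene identifiers.  Extended GPR rules add NOT literals contributed by
inhibitory regulatory interactions.  The grammar accepted by :func:`parse_gpr`
is the usual one::

    expr    := term (OR term)*
    term    := factor (AND factor)*
    factor  := NOT factor | '(' expr ')' | gene
    OR      := 'or' | '|'   AND := 'and' | '&'   NOT := 'not' | '!'

Keywords are case-insensitive; gene identifiers are any run of characters that
is not whitespace, a parenthesis or an operator symbol.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator


class BooleanExpr:
    """Abstract base for nodes of a Boolean expression tree."""

    def genes(self) -> set[str]:
        out: set[str] = set()
        _collect_genes(self, out)
        return out

    def evaluate(self, assignment: dict[str, bool]) -> bool:
        return _evaluate(self, assignment)

    def to_string(self) -> str:
        return _serialise(self, top=True)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({self.to_string()})"

    def __eq__(self, other) -> bool:
        return isinstance(other, BooleanExpr) and _key(self) == _key(other)

    def __hash__(self) -> int:
        return hash(_key(self))


@dataclass(frozen=True, eq=False)
class Var(BooleanExpr):
    name: str


@dataclass(frozen=True, eq=False)
class Not(BooleanExpr):
    arg: BooleanExpr


@dataclass(frozen=True, eq=False)
class And(BooleanExpr):
    args: tuple[BooleanExpr, ...]

    def __init__(self, *args: BooleanExpr):
        object.__setattr__(self, "args", _flatten(And, args))


@dataclass(frozen=True, eq=False)
class Or(BooleanExpr):
    args: tuple[BooleanExpr, ...]

    def __init__(self, *args: BooleanExpr):
        object.__setattr__(self, "args", _flatten(Or, args))


def _flatten(cls, args) -> tuple[BooleanExpr, ...]:
    out: list[BooleanExpr] = []
    for a in args:
        if isinstance(a, cls):
            out.extend(a.args)
        else:
            out.append(a)
    if not out:
        raise ValueError(f"{cls.__name__} requires at least one argument")
    return tuple(out)


def _key(e: BooleanExpr):
    if isinstance(e, Var):
        return ("v", e.name)
    if isinstance(e, Not):
        return ("n", _key(e.arg))
    if isinstance(e, And):
        return ("a",) + tuple(_key(a) for a in e.args)
    if isinstance(e, Or):
        return ("o",) + tuple(_key(a) for a in e.args)
    raise TypeError(e)


def _collect_genes(e: BooleanExpr, out: set[str]) -> None:
    if isinstance(e, Var):
        out.add(e.name)
    elif isinstance(e, Not):
        _collect_genes(e.arg, out)
    else:
        for a in e.args:
            _collect_genes(a, out)


def _evaluate(e: BooleanExpr, asg: dict[str, bool]) -> bool:
    if isinstance(e, Var):
        return bool(asg[e.name])
    if isinstance(e, Not):
        return not _evaluate(e.arg, asg)
    if isinstance(e, And):
        return all(_evaluate(a, asg) for a in e.args)
    return any(_evaluate(a, asg) for a in e.args)


def _serialise(e: BooleanExpr, top: bool = False) -> str:
    if isinstance(e, Var):
        return e.name
    if isinstance(e, Not):
        inner = _serialise(e.arg)
        if not isinstance(e.arg, Var):
            inner = f"({inner})"
        return f"not {inner}"
    op = " and " if isinstance(e, And) else " or "
    parts = []
    for a in e.args:
        s = _serialise(a)
        if isinstance(a, (And, Or)):
            s = f"({s})"
        parts.append(s)
    body = op.join(parts)
    return body if top else body


def to_nnf(e: BooleanExpr, negate: bool = False) -> BooleanExpr:
    """Push negations down to the literals (negation normal form)."""
    if isinstance(e, Var):
        return Not(e) if negate else e
    if isinstance(e, Not):
        return to_nnf(e.arg, not negate)
    cls = (Or if isinstance(e, And) else And) if negate else type(e)
    return cls(*(to_nnf(a, negate) for a in e.args))


def contains_not(e: BooleanExpr) -> bool:
    if isinstance(e, Not):
        return True
    if isinstance(e, Var):
        return False
    return any(contains_not(a) for a in e.args)


class GPRParseError(ValueError):
    """Raised for malformed rule strings; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_TOKEN = re.compile(r"\s*(\(|\)|&|\||!|[^\s()&|!]+)")


def _tokenise(text: str) -> Iterator[tuple[str, int]]:
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            break
        yield m.group(1), m.start(1)
        pos = m.end()


def parse_gpr(text: str) -> BooleanExpr:
    """Parse a GPR / eGPR rule string into a :class:`BooleanExpr`.

    Raises :class:`GPRParseError` on unbalanced parentheses or dangling
    operators, naming the character position.
    """
    tokens = list(_tokenise(text))
    if not tokens:
        raise GPRParseError("empty rule", 0)
    state = {"i": 0}

    def peek():
        return tokens[state["i"]] if state["i"] < len(tokens) else (None, len(text))

    def advance():
        tok = tokens[state["i"]]
        state["i"] += 1
        return tok

    def kind(tok: str) -> str:
        low = tok.lower()
        if tok == "(" or tok == ")":
            return tok
        if low == "and" or tok == "&":
            return "AND"
        if low == "or" or tok == "|":
            return "OR"
        if low == "not" or tok == "!":
            return "NOT"
        return "GENE"

    def parse_expr() -> BooleanExpr:
        terms = [parse_term()]
        while peek()[0] is not None and kind(peek()[0]) == "OR":
            advance()
            terms.append(parse_term())
        return terms[0] if len(terms) == 1 else Or(*terms)

    def parse_term() -> BooleanExpr:
        factors = [parse_factor()]
        while peek()[0] is not None and kind(peek()[0]) == "AND":
            advance()
            factors.append(parse_factor())
        return factors[0] if len(factors) == 1 else And(*factors)

    def parse_factor() -> BooleanExpr:
        tok, pos = peek()
        if tok is None:
            raise GPRParseError("unexpected end of rule", pos)
        k = kind(tok)
        if k == "NOT":
            advance()
            return Not(parse_factor())
        if k == "(":
            advance()
            inner = parse_expr()
            tok2, pos2 = peek()
            if tok2 != ")":
                raise GPRParseError("unbalanced parentheses", pos2)
            advance()
            return inner
        if k == "GENE":
            advance()
            return Var(tok)
        raise GPRParseError(f"unexpected token {tok!r}", pos)

    expr = parse_expr()
    tok, pos = peek()
    if tok is not None:
        raise GPRParseError(f"unexpected token {tok!r}", pos)
    return expr
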