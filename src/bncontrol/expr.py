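"""Boolean update-function expressions.

Update rules of a Boolean network are trees over AND / OR / NOT, node-name
references and the constants 0/1.  The textual grammar is

    orexpr   := andexpr ( "|" andexpr )*
    andexpr  := notexpr ( "&" notexpr )*
    notexpr  := "!" notexpr | atom
    atom     := "0" | "1" | identifier | "(" orexpr ")"

with precedence ``!`` > ``&`` > ``|``.  Identifiers match
``[A-Za-z][A-Za-z0-9_-]*`` (gene names such as ``ZAP-70`` are legal).  The
Unicode operators ``∧ ∨ ¬`` are accepted on input; the writer emits ASCII.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

__all__ = [
    "BoolExpr",
    "And",
    "Or",
    "Not",
    "Var",
    "Const",
    "ExpressionSyntaxError",
    "parse_expression",
    "evaluate",
    "variables",
    "render",
]


class ExpressionSyntaxError(ValueError):
    """Raised for malformed formula text; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class Var:
    name: str


@dataclass(frozen=True)
class Const:
    value: int  # 0 or 1


@dataclass(frozen=True)
class Not:
    child: "BoolExpr"


@dataclass(frozen=True)
class And:
    children: tuple["BoolExpr", ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("AND requires at least two children")


@dataclass(frozen=True)
class Or:
    children: tuple["BoolExpr", ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("OR requires at least two children")


BoolExpr = Var | Const | Not | And | Or

_IDENT_START = set("ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz")
_IDENT_CONT = _IDENT_START | set("0123456789_-")

# Unicode aliases accepted on input.
_ALIASES = {"∧": "&", "∨": "|", "¬": "!"}


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, msg: str) -> ExpressionSyntaxError:
        return ExpressionSyntaxError(msg, self.pos)

    def peek(self) -> str | None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1
        if self.pos >= len(self.text):
            return None
        ch = self.text[self.pos]
        return _ALIASES.get(ch, ch)

    def take(self) -> str:
        ch = self.peek()
        assert ch is not None
        self.pos += 1
        return ch

    def parse(self) -> BoolExpr:
        expr = self.or_expr()
        if self.peek() is not None:
            raise self.error(f"unexpected character {self.text[self.pos]!r}")
        return expr

    def or_expr(self) -> BoolExpr:
        terms = [self.and_expr()]
        while self.peek() == "|":
            self.take()
            terms.append(self.and_expr())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def and_expr(self) -> BoolExpr:
        terms = [self.not_expr()]
        while self.peek() == "&":
            self.take()
            terms.append(self.not_expr())
        return terms[0] if len(terms) == 1 else And(tuple(terms))

    def not_expr(self) -> BoolExpr:
        if self.peek() == "!":
            self.take()
            return Not(self.not_expr())
        return self.atom()

    def atom(self) -> BoolExpr:
        ch = self.peek()
        if ch is None:
            raise self.error("unexpected end of formula")
        if ch == "(":
            self.take()
            inner = self.or_expr()
            if self.peek() != ")":
                raise self.error("expected ')'")
            self.take()
            return inner
        if ch in "01":
            self.take()
            return Const(int(ch))
        if ch in _IDENT_START:
            start = self.pos
            self.pos += 1
            while self.pos < len(self.text) and self.text[self.pos] in _IDENT_CONT:
                self.pos += 1
            return Var(self.text[start : self.pos])
        raise self.error(f"unexpected character {self.text[self.pos]!r}")


def parse_expression(text: str) -> BoolExpr:
    """Parse formula text into an expression tree.

    Raises :class:`ExpressionSyntaxError` (with position) on malformed input.
    References to undeclared nodes are not checked here; that is network-level
    validation.
    """
    return _Parser(text).parse()


def evaluate(expr: BoolExpr, assignment: Mapping[str, int]) -> int:
    """Evaluate ``expr`` under a total 0/1 assignment; pure.

    Raises ``KeyError`` if a referenced variable is missing.
    """
    match expr:
        case Const(value=v):
            return v
        case Var(name=name):
            return int(assignment[name])
        case Not(child=c):
            return 1 - evaluate(c, assignment)
        case And(children=cs):
            for c in cs:
                if not evaluate(c, assignment):
                    return 0
            return 1
        case Or(children=cs):
            for c in cs:
                if evaluate(c, assignment):
                    return 1
            return 0
    raise TypeError(f"not a boolean expression: {expr!r}")


def variables(expr: BoolExpr) -> tuple[str, ...]:
    """Distinct variable names referenced by ``expr``, in first-occurrence order."""
    seen: dict[str, None] = {}

    def walk(e: BoolExpr) -> None:
        match e:
            case Var(name=name):
                seen.setdefault(name)
            case Not(child=c):
                walk(c)
            case And(children=cs) | Or(children=cs):
                for c in cs:
                    walk(c)

    walk(expr)
    return tuple(seen)


def _render(expr: BoolExpr, parent_prec: int) -> str:
    # precedence levels: Or=1, And=2, Not=3, atoms=4
    match expr:
        case Const(value=v):
            return str(v)
        case Var(name=name):
            return name
        case Not(child=c):
            return "!" + _render(c, 3)
        case And(children=cs):
            body = " & ".join(_render(c, 2) for c in cs)
            return f"({body})" if parent_prec > 2 else body
        case Or(children=cs):
            body = " | ".join(_render(c, 1) for c in cs)
            return f"({body})" if parent_prec > 1 else body
    raise TypeError(f"not a boolean expression: {expr!r}")


def render(expr: BoolExpr) -> str:
    """Render to ASCII text; ``parse_expression(render(e))`` is truth-table equal to ``e``."""
    return _render(expr, 0)


def python_source(expr: BoolExpr, name_to_ref: Mapping[str, str]) -> str:
    """Translate to a Python int expression over the given variable references.

    Used to compile whole-network transition functions and the bit-parallel
    oracle; each variable reference string must already be valid Python.
    """
    match expr:
        case Const(value=v):
            return "FULL" if v else "0"
        case Var(name=name):
            return name_to_ref[name]
        case Not(child=c):
            return f"(FULL ^ {python_source(c, name_to_ref)})"
        case And(children=cs):
            return "(" + " & ".join(python_source(c, name_to_ref) for c in cs) + ")"
        case Or(children=cs):
            return "(" + " | ".join(python_source(c, name_to_ref) for c in cs) + ")"
    raise TypeError(f"not a boolean expression: {expr!r}")


def iter_assignments(names: tuple[str, ...]) -> Iterator[dict[str, int]]:
    """All 2^k assignments over ``names``, in binary-counting order (first name = LSB)."""
    for code in range(1 << len(names)):
        yield {n: (code >> i) & 1 for i, n in enumerate(names)}
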