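"""Reading and writing Boolean-network model files.

The interchange format is the plain-text dialect used by the common
Boolean-network tool ecosystem: a header line ``targets, factors``,
then one line per node of the form ``NODE, <expression>`` where ``&``
is AND, ``|`` is OR, ``!`` is NOT, parentheses group, and the bare
constants ``0``/``1`` are allowed.  Lines starting with ``#`` are
comments.  Node order in the file defines the state encoding of the
parsed model.  Operator precedence is the standard NOT > AND > OR.

Round-trip stability is a contract: ``parse_model(write_model(m))``
has identical node order and rules, hence an identical state-transition
graph.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path

from .engine import (
    And,
    Const,
    Expr,
    ModelValidationError,
    NetworkModel,
    Not,
    Or,
    Var,
)

__all__ = [
    "BoolNetSyntaxError",
    "parse_model",
    "write_model",
    "load_model",
    "save_model",
    "packaged_model_names",
    "packaged_model",
    "format_expression",
]

PACKAGED_MODELS = ("core_medial", "extended_medial", "lateral")

_IDENT = r"[A-Za-z_][A-Za-z0-9_.]*"
_TOKEN_RE = re.compile(
    rf"\s*(?:(?P<ident>{_IDENT})|(?P<const>[01])|(?P<op>[&|!()]))")


class BoolNetSyntaxError(ValueError):
    """Malformed model file; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def _tokenize(text: str, line: int) -> list:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise BoolNetSyntaxError(
                    f"unexpected character {text[pos:].strip()[0]!r}", line)
            break
        if m.group("ident"):
            tokens.append(("ident", m.group("ident")))
        elif m.group("const"):
            tokens.append(("const", int(m.group("const"))))
        else:
            tokens.append(("op", m.group("op")))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser; grammar OR := AND ('|' AND)*,
    AND := UNARY ('&' UNARY)*, UNARY := '!' UNARY | '(' OR ')' | atom."""

    def __init__(self, tokens, line):
        self.tokens = tokens
        self.line = line
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        if tok is None:
            raise BoolNetSyntaxError("unexpected end of expression",
                                     self.line)
        self.i += 1
        return tok

    def parse(self) -> Expr:
        expr = self.parse_or()
        if self.peek() is not None:
            raise BoolNetSyntaxError(
                f"trailing input near {self.peek()[1]!r}", self.line)
        return expr

    def parse_or(self) -> Expr:
        operands = [self.parse_and()]
        while self.peek() == ("op", "|"):
            self.take()
            operands.append(self.parse_and())
        return operands[0] if len(operands) == 1 else Or(tuple(operands))

    def parse_and(self) -> Expr:
        operands = [self.parse_unary()]
        while self.peek() == ("op", "&"):
            self.take()
            operands.append(self.parse_unary())
        return operands[0] if len(operands) == 1 else And(tuple(operands))

    def parse_unary(self) -> Expr:
        kind, value = self.take()
        if (kind, value) == ("op", "!"):
            return Not(self.parse_unary())
        if (kind, value) == ("op", "("):
            expr = self.parse_or()
            if self.take() != ("op", ")"):
                raise BoolNetSyntaxError("expected ')'", self.line)
            return expr
        if kind == "ident":
            return Var(value)
        if kind == "const":
            return Const(value)
        raise BoolNetSyntaxError(f"unexpected token {value!r}", self.line)


def parse_model(text: str, metadata: dict | None = None) -> NetworkModel:
    """Parse a model file; node order follows file order.

    Syntax errors and references to undeclared nodes are reported with
    their 1-based line number.
    """
    header_seen = False
    entries = []  # (line_no, name, expr)
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            if re.fullmatch(r"targets\s*,\s*factors", line, re.IGNORECASE):
                header_seen = True
                continue
            raise BoolNetSyntaxError(
                "expected header 'targets, factors'", line_no)
        if "," not in line:
            raise BoolNetSyntaxError(
                "expected 'NODE, expression'", line_no)
        name, _, expr_text = line.partition(",")
        name = name.strip()
        if not re.fullmatch(_IDENT, name):
            raise BoolNetSyntaxError(f"invalid node name {name!r}", line_no)
        expr = _Parser(_tokenize(expr_text, line_no), line_no).parse()
        entries.append((line_no, name, expr))
    if not header_seen:
        raise BoolNetSyntaxError("empty model file (no header)", 1)
    if not entries:
        raise BoolNetSyntaxError("model file declares no nodes", 1)
    declared = {name for _, name, _ in entries}
    for line_no, name, expr in entries:
        if sum(1 for _, other, _ in entries if other == name) > 1:
            raise BoolNetSyntaxError(f"duplicate node {name!r}", line_no)
        unknown = expr.variables() - declared
        if unknown:
            raise BoolNetSyntaxError(
                f"rule for {name} references undeclared node(s) "
                f"{', '.join(sorted(unknown))}", line_no)
    return NetworkModel(
        nodes=[name for _, name, _ in entries],
        rules={name: expr for _, name, expr in entries},
        metadata=metadata,
    )


# precedence levels for canonical formatting
_PREC_OR, _PREC_AND, _PREC_NOT = 1, 2, 3


def format_expression(expr: Expr, parent_prec: int = 0) -> str:
    """Render an expression in the file dialect, minimally parenthesized."""
    if isinstance(expr, Const):
        return str(expr.value)
    if isinstance(expr, Var):
        return expr.name
    if isinstance(expr, Not):
        text = "!" + format_expression(expr.operand, _PREC_NOT)
        prec = _PREC_NOT
    elif isinstance(expr, And):
        text = " & ".join(format_expression(o, _PREC_AND)
                          for o in expr.operands)
        prec = _PREC_AND
    elif isinstance(expr, Or):
        text = " | ".join(format_expression(o, _PREC_OR)
                          for o in expr.operands)
        prec = _PREC_OR
    else:
        raise TypeError(f"unknown expression type {type(expr)!r}")
    return f"({text})" if prec < parent_prec else text


def write_model(model: NetworkModel) -> str:
    """Serialize a model canonically (UTF-8 text, Unix newlines)."""
    lines = ["targets, factors"]
    for name in model.nodes:
        lines.append(f"{name}, {format_expression(model.rules[name])}")
    return "\n".join(lines) + "\n"


def load_model(path) -> NetworkModel:
    path = Path(path)
    return parse_model(path.read_text(encoding="utf-8"),
                       metadata={"source": str(path)})


def save_model(model: NetworkModel, path) -> None:
    Path(path).write_text(write_model(model), encoding="utf-8")


def packaged_model_names() -> tuple:
    return PACKAGED_MODELS


def packaged_model(name: str) -> NetworkModel:
    """Load one of the shipped model files (parsed, with alias metadata
    so motif collapsing works on the parsed model too)."""
    if name not in PACKAGED_MODELS:
        raise ValueError(f"unknown packaged model {name!r}; expected one "
                         f"of {PACKAGED_MODELS}")
    text = (resources.files("gynogrn") / "data" / f"{name}.bnet"
            ).read_text(encoding="utf-8")
    return parse_model(text, metadata={"variant": name,
                                       "aliases": {"ARR1P": "ARR1"}})
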