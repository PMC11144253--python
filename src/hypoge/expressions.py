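"""Rule models: the if-then-else conditions evolved by the engines.

A decoded phenotype is a boolean condition over lagged clinical variables
(``gluc_s``, ``hr_s``, ``steps_s``, ``cal_s`` with the lag ``s`` in minutes),
three-decimal constants, arithmetic (+ - * /), relational (< > <= >=) and
logical (&& ||) operators.  A window whose condition evaluates true is
classified as hypoglycemia.

Arithmetic is *protected*: division by zero yields 1.0, so every expression
evaluates to a finite number on finite inputs (steps and calories are
legitimately zero at rest, and evolved expressions routinely divide by
them).

The module also builds the default grammar that generates exactly this
expression language.  Constants are digit-encoded in the grammar (assembled
from digit productions at decode time), which keeps genotype-to-phenotype
decoding a pure function of the genotype and lets integer-flip mutation
make local moves on constant values.  Two constant shapes are offered in
every numeric context: a glucose-scale literal in [0, 400) and a unit-scale
literal in [0, 10), both with three decimals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

from .grammar import Grammar, parse_bnf

__all__ = [
    "Var",
    "Const",
    "BinOp",
    "Rel",
    "Bool",
    "RuleModel",
    "ExpressionError",
    "PhenotypeSyntaxError",
    "parse_phenotype",
    "default_grammar",
    "load_default_grammar",
    "default_variable_subsets",
    "variable_names",
    "variable_usage",
    "select_lags_by_correlation",
    "HYPOGLYCEMIA",
    "NON_HYPOGLYCEMIA",
]

HYPOGLYCEMIA = "hypoglycemia"
NON_HYPOGLYCEMIA = "non-hypoglycemia"

CHANNELS = ("gluc", "hr", "steps", "cal")


class ExpressionError(ValueError):
    """Evaluation failure: a referenced variable is missing from the window."""


class PhenotypeSyntaxError(ValueError):
    """Malformed phenotype text; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# ---------------------------------------------------------------------------
# Expression tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Var:
    name: str  # e.g. "gluc_0", "hr_15"


@dataclass(frozen=True)
class Const:
    value: float
    text: str  # literal as written, preserved for exact round-trips


@dataclass(frozen=True)
class BinOp:
    op: str  # + - * /
    left: "Expr"
    right: "Expr"


@dataclass(frozen=True)
class Rel:
    op: str  # < > <= >=
    left: "Expr"
    right: "Expr"


@dataclass(frozen=True)
class Bool:
    op: str  # && ||
    left: "Expr"
    right: "Expr"


Expr = Union[Var, Const, BinOp, Rel, Bool]


def _walk(node: Expr):
    yield node
    for attr in ("left", "right"):
        child = getattr(node, attr, None)
        if child is not None:
            yield from _walk(child)


def _serialize(node: Expr) -> str:
    if isinstance(node, Var):
        return node.name
    if isinstance(node, Const):
        return node.text
    if isinstance(node, BinOp):
        return f"({_serialize(node.left)}{node.op}{_serialize(node.right)})"
    if isinstance(node, Rel):
        return f"{_serialize(node.left)}{node.op}{_serialize(node.right)}"
    if isinstance(node, Bool):
        return f"({_serialize(node.left)}{node.op}{_serialize(node.right)})"
    raise TypeError(f"not an expression node: {node!r}")


def _pretty(node: Expr) -> str:
    if isinstance(node, (Var, Const)):
        return _serialize(node)
    if isinstance(node, Rel):
        return f"{_pretty(node.left)} {node.op} {_pretty(node.right)}"
    return f"({_pretty(node.left)} {node.op} {_pretty(node.right)})"


def _compile(node: Expr):
    """Build a closure mapping {name: ndarray} -> ndarray (protected ops)."""
    if isinstance(node, Var):
        name = node.name

        def var_fn(data, _name=name):
            try:
                return data[_name]
            except KeyError:
                raise ExpressionError(f"variable {_name!r} missing from window")

        return var_fn
    if isinstance(node, Const):
        value = node.value
        return lambda data, _v=value: _v
    left = _compile(node.left)
    right = _compile(node.right)
    op = node.op
    if isinstance(node, BinOp):
        if op == "+":
            return lambda d: left(d) + right(d)
        if op == "-":
            return lambda d: left(d) - right(d)
        if op == "*":
            return lambda d: left(d) * right(d)
        if op == "/":

            def protected_div(d):
                num, den = left(d), right(d)
                if np.isscalar(num) and np.isscalar(den):
                    return num / den if den != 0 else 1.0
                num = np.asarray(num, dtype=float)
                den = np.asarray(den, dtype=float)
                zero = den == 0
                safe = np.where(zero, 1.0, den)
                return np.where(zero, 1.0, np.asarray(num) / safe)

            return protected_div
        raise ValueError(f"unknown arithmetic operator {op!r}")
    if isinstance(node, Rel):
        if op == "<":
            return lambda d: left(d) < right(d)
        if op == ">":
            return lambda d: left(d) > right(d)
        if op == "<=":
            return lambda d: left(d) <= right(d)
        if op == ">=":
            return lambda d: left(d) >= right(d)
        raise ValueError(f"unknown relational operator {op!r}")
    if isinstance(node, Bool):
        if op == "&&":
            return lambda d: left(d) & right(d)
        if op == "||":
            return lambda d: left(d) | right(d)
        raise ValueError(f"unknown logical operator {op!r}")
    raise TypeError(f"not an expression node: {node!r}")


@dataclass(frozen=True, eq=False)
class RuleModel:
    """A decoded classifier: a boolean condition; true means hypoglycemia."""

    condition: Expr

    def __post_init__(self) -> None:
        if not isinstance(self.condition, (Rel, Bool)):
            raise ValueError("a rule's condition must be boolean-valued")
        object.__setattr__(self, "_fn", _compile(self.condition))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RuleModel):
            return NotImplemented
        return self.condition == other.condition

    def evaluate(self, window: Mapping[str, float]) -> str:
        """Classify one complete feature window."""
        return HYPOGLYCEMIA if bool(self._fn(window)) else NON_HYPOGLYCEMIA

    def predict(self, data) -> np.ndarray:
        """Vectorised classification: boolean array, True = hypoglycemia.

        ``data`` is a mapping of variable name to 1-D array (a pandas
        DataFrame works via column access).  Constant conditions broadcast
        to the number of rows.
        """
        out = np.asarray(self._fn(data), dtype=bool)
        if out.ndim == 0:
            if isinstance(data, Mapping):
                n = len(next(iter(data.values())))
            else:
                n = len(data)
            out = np.full(n, bool(out))
        return out

    def variables(self) -> set[str]:
        return {n.name for n in _walk(self.condition) if isinstance(n, Var)}

    def serialize(self) -> str:
        """Canonical phenotype text; parses back to an equal model."""
        return _serialize(self.condition)

    def __str__(self) -> str:
        return _pretty(self.condition)


# ---------------------------------------------------------------------------
# Phenotype parser (precedence climbing over a tiny lexer)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<number>\d+\.\d+|\d+)"
    r"|(?P<ident>[A-Za-z][A-Za-z0-9]*_\d+)"
    r"|(?P<op>&&|\|\||<=|>=|<|>|\+|-|\*|/|\(|\)))"
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip() == "":
                break
            raise PhenotypeSyntaxError(
                f"unexpected character {text[pos]!r}", pos
            )
        kind = m.lastgroup
        tokens.append((kind, m.group(kind), m.start(kind)))
        pos = m.end()
    return tokens


class _Parser:
    """Precedence: || < && < relational < (+ -) < (* /) < primary."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is None:
            raise PhenotypeSyntaxError("unexpected end of input", len(self.text))
        self.i += 1
        return tok

    def expect_op(self, op: str):
        tok = self.next()
        if tok[0] != "op" or tok[1] != op:
            raise PhenotypeSyntaxError(f"expected {op!r}, got {tok[1]!r}", tok[2])

    def parse(self) -> Expr:
        node = self.or_expr()
        tok = self.peek()
        if tok is not None:
            raise PhenotypeSyntaxError(f"trailing input {tok[1]!r}", tok[2])
        return node

    def or_expr(self) -> Expr:
        node = self.and_expr()
        while self._at("||"):
            self.next()
            node = Bool("||", self._boolean(node), self._boolean(self.and_expr()))
        return node

    def and_expr(self) -> Expr:
        node = self.rel_expr()
        while self._at("&&"):
            self.next()
            node = Bool("&&", self._boolean(node), self._boolean(self.rel_expr()))
        return node

    def rel_expr(self) -> Expr:
        node = self.add_expr()
        if self._at("<", ">", "<=", ">="):
            tok = self.next()
            rhs = self.add_expr()
            node = Rel(tok[1], self._numeric(node, tok[2]), self._numeric(rhs, tok[2]))
        return node

    def add_expr(self) -> Expr:
        node = self.mul_expr()
        while self._at("+", "-"):
            tok = self.next()
            node = BinOp(
                tok[1],
                self._numeric(node, tok[2]),
                self._numeric(self.mul_expr(), tok[2]),
            )
        return node

    def mul_expr(self) -> Expr:
        node = self.primary()
        while self._at("*", "/"):
            tok = self.next()
            node = BinOp(
                tok[1],
                self._numeric(node, tok[2]),
                self._numeric(self.primary(), tok[2]),
            )
        return node

    def primary(self) -> Expr:
        tok = self.next()
        kind, text, pos = tok
        if kind == "number":
            return Const(float(text), text)
        if kind == "ident":
            return Var(text)
        if kind == "op" and text == "(":
            node = self.or_expr()
            self.expect_op(")")
            return node
        raise PhenotypeSyntaxError(f"unexpected token {text!r}", pos)

    def _at(self, *ops: str) -> bool:
        tok = self.peek()
        return tok is not None and tok[0] == "op" and tok[1] in ops

    @staticmethod
    def _numeric(node: Expr, pos: int) -> Expr:
        if isinstance(node, (Rel, Bool)):
            raise PhenotypeSyntaxError(
                "boolean expression used where a number is required", pos
            )
        return node

    @staticmethod
    def _boolean(node: Expr) -> Expr:
        if not isinstance(node, (Rel, Bool)):
            raise PhenotypeSyntaxError(
                "numeric expression used where a condition is required", 0
            )
        return node


def parse_phenotype(text: str) -> RuleModel:
    """Parse phenotype text into a :class:`RuleModel`.

    Honors conventional precedence (``* /`` over ``+ -``; relational over
    logical; ``&&`` over ``||``; parentheses respected).  Raises
    :class:`PhenotypeSyntaxError` with a character position on bad input.
    """
    node = _Parser(text).parse()
    if not isinstance(node, (Rel, Bool)):
        raise PhenotypeSyntaxError(
            "phenotype is a bare numeric expression, not a condition", 0
        )
    return RuleModel(node)


# ---------------------------------------------------------------------------
# Default grammar
# ---------------------------------------------------------------------------

def default_variable_subsets() -> dict[str, list[int]]:
    """Per-channel lag subsets (minutes) used by the shipped grammar.

    Glucose keeps the prediction-time value and the previous 25 minutes at
    5-minute intervals — the newest trend is the strongest signal.  The
    activity-adjacent channels keep a spread over the full 2-hour history,
    where slower dynamics (a meal's worth of calories, an exercise bout)
    matter more than the newest sample.
    """
    return {
        "gluc": [0, 5, 10, 15, 20, 25],
        "hr": [0, 15, 30, 60, 90, 120],
        "steps": [0, 15, 30, 60, 90, 120],
        "cal": [0, 15, 30, 60, 90, 120],
    }


def variable_names(subsets: Mapping[str, Sequence[int]] | None = None) -> list[str]:
    subsets = subsets or default_variable_subsets()
    return [f"{ch}_{lag}" for ch in subsets for lag in subsets[ch]]


def default_grammar(
    variable_subsets: Mapping[str, Sequence[int]] | None = None,
    const_ranges: Mapping[str, float] | None = None,
) -> Grammar:
    """The grammar of hypoglycemia rule conditions.

    Its language is the set of fully parenthesised boolean expressions over
    relational comparisons of arithmetic expressions over the lagged
    variables and digit-encoded constants.  ``const_ranges`` maps
    ``{"glucose": 400, "unit": 10}`` to the (exclusive) upper bounds of the
    two constant shapes; only decade bounds 10/100/400 are supported for the
    glucose shape.
    """
    subsets = dict(variable_subsets or default_variable_subsets())
    ranges = {"glucose": 400.0, "unit": 10.0}
    if const_ranges:
        ranges.update(const_ranges)
    vars_: list[str] = []
    for ch, lags in subsets.items():
        if not lags:
            raise ValueError(f"channel {ch!r} has an empty lag subset")
        for lag in lags:
            if lag % 5 != 0 or not (0 <= lag <= 120):
                raise ValueError(
                    f"lag {lag} for {ch!r} not on the 5-minute grid in [0,120]"
                )
            vars_.append(f"{ch}_{lag}")

    digits = " | ".join(str(d) for d in range(10))
    gmax = ranges["glucose"]
    if gmax <= 10:
        gconst_alts = "<digit> . <digit> <digit> <digit>"
    elif gmax <= 100:
        gconst_alts = (
            "<digit> . <digit> <digit> <digit>"
            " | <digit> <digit> . <digit> <digit> <digit>"
        )
    else:
        hundreds = " | ".join(str(d) for d in range(1, int(gmax // 100)))
        gconst_alts = (
            "<digit> . <digit> <digit> <digit>"
            " | <digit> <digit> . <digit> <digit> <digit>"
            " | <hund> <digit> <digit> . <digit> <digit> <digit>"
        )
    lines = [
        "<cond> ::= <rel> | ( <cond> && <cond> ) | ( <cond> || <cond> )",
        "<rel> ::= <aexpr> <relop> <aexpr>",
        "<relop> ::= < | > | <= | >=",
        "<aexpr> ::= <operand> | ( <aexpr> <numop> <aexpr> )",
        "<numop> ::= + | - | * | /",
        "<operand> ::= <var> | <const>",
        "<var> ::= " + " | ".join(vars_),
        "<const> ::= <gconst> | <uconst>",
        "<gconst> ::= " + gconst_alts,
        "<uconst> ::= <digit> . <digit> <digit> <digit>",
        "<digit> ::= " + digits,
    ]
    if gmax > 100:
        lines.append("<hund> ::= " + hundreds)  # leading hundreds digit
    return parse_bnf("\n".join(lines))


def load_default_grammar() -> Grammar:
    """The packaged BNF file (identical to ``default_grammar()``)."""
    from importlib import resources

    text = (
        resources.files("hypoge.data").joinpath("hypo_grammar.bnf").read_text()
    )
    return parse_bnf(text)


# ---------------------------------------------------------------------------
# Analysis helpers
# ---------------------------------------------------------------------------

def variable_usage(models: Iterable[RuleModel]) -> dict[str, float]:
    """Fraction of models in which each variable appears at least once.

    Counts every variable that occurs in at least one model; variables a
    caller cares about but that never occur can be filled in as 0 from
    :func:`variable_names`.
    """
    models = list(models)
    if not models:
        raise ValueError("empty model collection")
    counts: dict[str, int] = {}
    for m in models:
        for v in m.variables():
            counts[v] = counts.get(v, 0) + 1
    return {v: c / len(models) for v, c in sorted(counts.items())}


def select_lags_by_correlation(
    series_values: Mapping[int, "np.ndarray"],
    threshold: float = 0.9,
) -> list[int]:
    """Greedy correlation-based lag selection for one channel.

    ``series_values`` maps lag (minutes) to the aligned lagged value array.
    Lags are scanned in increasing order; a lag is kept unless its absolute
    Pearson correlation with an already-kept lag exceeds ``threshold``.
    """
    kept: list[int] = []
    for lag in sorted(series_values):
        x = np.asarray(series_values[lag], dtype=float)
        redundant = False
        for k in kept:
            y = np.asarray(series_values[k], dtype=float)
            mask = np.isfinite(x) & np.isfinite(y)
            if mask.sum() < 3:
                continue
            xm, ym = x[mask], y[mask]
            if xm.std() == 0 or ym.std() == 0:
                continue
            r = float(np.corrcoef(xm, ym)[0, 1])
            if abs(r) > threshold:
                redundant = True
                break
        if not redundant:
            kept.append(lag)
    return kept
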