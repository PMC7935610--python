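"""Row filters over event tables.

The filter language is deliberately tiny: comparisons between a column
name and a numeric or quoted-string literal, combined with ``and`` /
``or`` and parentheses, e.g. ``Case > 10 and RelativeTime < 380``.

Filtering happens *after* relative-time derivation and does not re-anchor
``RelativeTime``: a filter on relative time itself (as in the example
above) only makes sense against the pre-filter anchor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .errors import FilterError
from .io import EventTable

_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<lparen>\()
      | (?P<rparen>\))
      | (?P<op><=|>=|==|!=|<|>)
      | (?P<number>-?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?)
      | (?P<string>'[^']*'|"[^"]*")
      | (?P<name>[A-Za-z_][A-Za-z0-9_]*)
    )""",
    re.VERBOSE,
)

_OPS = {
    "<": np.less,
    "<=": np.less_equal,
    ">": np.greater,
    ">=": np.greater_equal,
    "==": np.equal,
    "!=": np.not_equal,
}


@dataclass
class _Token:
    kind: str
    value: str
    pos: int


def _tokenize(expression: str) -> list[_Token]:
    tokens, pos = [], 0
    while pos < len(expression):
        m = _TOKEN_RE.match(expression, pos)
        if m is None or m.end() == pos:
            stripped = expression[pos:].lstrip()
            if not stripped:
                break
            bad_at = len(expression) - len(stripped)
            raise FilterError(
                f"syntax error at position {bad_at}: unexpected {stripped[0]!r}"
            )
        group = m.lastgroup
        value = m.group(group)
        start = m.start(group)
        kind = value if group == "name" and value in ("and", "or") else group
        tokens.append(_Token(kind, value, start))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser evaluating directly to a boolean mask."""

    def __init__(self, tokens: list[_Token], df: pd.DataFrame, expression: str):
        self.tokens = tokens
        self.df = df
        self.expression = expression
        self.i = 0

    def peek(self) -> Union[_Token, None]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise FilterError(
                f"syntax error at position {len(self.expression)}: unexpected end of expression"
            )
        self.i += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        tok = self.peek()
        if tok is not None:
            raise FilterError(f"syntax error at position {tok.pos}: unexpected {tok.value!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while (tok := self.peek()) is not None and tok.kind == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while (tok := self.peek()) is not None and tok.kind == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.next()
        if tok.kind == "lparen":
            mask = self.expr()
            closing = self.next()
            if closing.kind != "rparen":
                raise FilterError(
                    f"syntax error at position {closing.pos}: expected ')'"
                )
            return mask
        if tok.kind == "name":
            return self.comparison(tok)
        raise FilterError(f"syntax error at position {tok.pos}: unexpected {tok.value!r}")

    def comparison(self, name_tok: _Token) -> np.ndarray:
        if name_tok.value not in self.df.columns:
            raise FilterError(f"unknown column {name_tok.value!r}")
        op_tok = self.next()
        if op_tok.kind != "op":
            raise FilterError(
                f"syntax error at position {op_tok.pos}: expected comparison operator"
            )
        lit_tok = self.next()
        column = self.df[name_tok.value]
        if lit_tok.kind == "number":
            literal: Union[float, str] = float(lit_tok.value)
            values = pd.to_numeric(column, errors="coerce").to_numpy()
        elif lit_tok.kind == "string":
            literal = lit_tok.value[1:-1]
            values = column.astype(str).to_numpy()
            if op_tok.value not in ("==", "!="):
                # lexicographic comparison on strings is permitted but rarely wanted
                values = values.astype(str)
        else:
            raise FilterError(
                f"syntax error at position {lit_tok.pos}: expected a literal, got {lit_tok.value!r}"
            )
        return np.asarray(_OPS[op_tok.value](values, literal), dtype=bool)


def filter_mask(events: EventTable, expression: str) -> np.ndarray:
    """Evaluate a filter expression to a boolean row mask."""
    tokens = _tokenize(expression)
    if not tokens:
        raise FilterError("empty filter expression")
    return _Parser(tokens, events.df, expression).parse()


def apply_filter(events: EventTable, expression: str) -> EventTable:
    """Return the rows for which the expression holds.

    Derived columns are *not* recomputed: ``RelativeTime`` keeps its
    pre-filter values.

    Raises
    ------
    FilterError
        Unknown column name, or a syntax error with its position.
    """
    mask = filter_mask(events, expression)
    return EventTable(events.df.loc[mask].reset_index(drop=True))
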