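"""Boolean update rules: a small expression grammar and truth-table semantics.

A rule is a pure function of an ordered tuple of parent nodes.  Internally every
rule is normalised to a truth table of length ``2**len(parents)``; the table is
indexed with parent ``i`` contributing bit ``i`` (least significant bit first),
i.e. ``index = sum(value[parents[i]] << i)``.

The human-writable expression grammar is deliberately tiny::

    expr   := term ('|' term)*
    term   := factor ('&' factor)*
    factor := '!' factor | '(' expr ')' | '0' | '1' | identifier

Identifiers match ``[A-Za-z_][A-Za-z0-9_]*``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import RuleSyntaxError

_TOKEN_RE = re.compile(r"\s*(?:([A-Za-z_][A-Za-z0-9_]*)|([01])|([&|!()]))")


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise RuleSyntaxError(
                f"unexpected character {text[pos]!r} at position {pos} in rule {text!r}"
            )
        tokens.append(m.group(1) or m.group(2) or m.group(3))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser producing a nested-tuple AST.

    AST nodes: ("var", name) | ("const", 0|1) | ("not", a) | ("and", a, b) |
    ("or", a, b).
    """

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> str | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise RuleSyntaxError(f"unexpected end of rule {self.text!r}")
        self.i += 1
        return tok

    def parse(self):
        node = self.expr()
        if self.peek() is not None:
            raise RuleSyntaxError(
                f"trailing token {self.peek()!r} in rule {self.text!r}"
            )
        return node

    def expr(self):
        node = self.term()
        while self.peek() == "|":
            self.take()
            node = ("or", node, self.term())
        return node

    def term(self):
        node = self.factor()
        while self.peek() == "&":
            self.take()
            node = ("and", node, self.factor())
        return node

    def factor(self):
        tok = self.take()
        if tok == "!":
            return ("not", self.factor())
        if tok == "(":
            node = self.expr()
            if self.take() != ")":
                raise RuleSyntaxError(f"missing ')' in rule {self.text!r}")
            return node
        if tok in ("0", "1"):
            return ("const", int(tok))
        if tok in ("&", "|", ")"):
            raise RuleSyntaxError(
                f"unexpected operator {tok!r} in rule {self.text!r}"
            )
        return ("var", tok)


def _ast_vars(node, out: list[str]) -> None:
    kind = node[0]
    if kind == "var":
        if node[1] not in out:
            out.append(node[1])
    elif kind == "not":
        _ast_vars(node[1], out)
    elif kind in ("and", "or"):
        _ast_vars(node[1], out)
        _ast_vars(node[2], out)


def _ast_eval(node, env: Mapping[str, int]) -> int:
    kind = node[0]
    if kind == "var":
        return env[node[1]]
    if kind == "const":
        return node[1]
    if kind == "not":
        return 1 - _ast_eval(node[1], env)
    if kind == "and":
        return _ast_eval(node[1], env) & _ast_eval(node[2], env)
    return _ast_eval(node[1], env) | _ast_eval(node[2], env)


@dataclass(frozen=True)
class BooleanRule:
    """An update rule over an ordered tuple of parent node ids.

    ``table[i]`` is the rule output when parent ``j`` has the value of bit
    ``j`` of ``i`` (LSB first).  ``expression`` is kept when the rule was
    authored as text; it is advisory — the table is the semantics.
    """

    parents: tuple[str, ...]
    table: tuple[int, ...]
    expression: str | None = field(default=None, compare=False)

    def __post_init__(self):
        if len(self.table) != 1 << len(self.parents):
            raise ValueError(
                f"truth table length {len(self.table)} != 2**{len(self.parents)}"
            )
        if any(v not in (0, 1) for v in self.table):
            raise ValueError("truth table entries must be 0/1")
        if len(set(self.parents)) != len(self.parents):
            raise ValueError("duplicate parent ids")

    @classmethod
    def from_expression(
        cls, expression: str, parents: Sequence[str] | None = None
    ) -> "BooleanRule":
        """Build a rule from an expression; parents default to the order of
        first appearance in the expression."""
        ast = _Parser(expression).parse()
        referenced: list[str] = []
        _ast_vars(ast, referenced)
        if parents is None:
            parents = referenced
        else:
            missing = set(referenced) - set(parents)
            if missing:
                raise RuleSyntaxError(
                    f"rule {expression!r} references non-parents {sorted(missing)}"
                )
        parents = tuple(parents)
        k = len(parents)
        table = []
        for idx in range(1 << k):
            env = {p: (idx >> j) & 1 for j, p in enumerate(parents)}
            table.append(_ast_eval(ast, env))
        return cls(parents=parents, table=tuple(table), expression=expression)

    @classmethod
    def from_table(
        cls, parents: Sequence[str], table: Iterable[int]
    ) -> "BooleanRule":
        return cls(parents=tuple(parents), table=tuple(int(v) for v in table))

    @classmethod
    def constant(cls, value: int) -> "BooleanRule":
        return cls(parents=(), table=(int(value),), expression=str(int(value)))

    @classmethod
    def identity(cls, node_id: str) -> "BooleanRule":
        """Self-maintaining rule: the node copies its own previous value."""
        return cls(parents=(node_id,), table=(0, 1), expression=node_id)

    def evaluate(self, env: Mapping[str, int]) -> int:
        idx = 0
        for j, p in enumerate(self.parents):
            idx |= (env[p] & 1) << j
        return self.table[idx]

    def to_expression(self) -> str:
        """Render as an expression; minterm (DNF) form when no authored
        expression is available."""
        if self.expression is not None:
            return self.expression
        if not self.parents:
            return str(self.table[0])
        minterms = [i for i, v in enumerate(self.table) if v == 1]
        if not minterms:
            return "0"
        if len(minterms) == len(self.table):
            return "1"
        terms = []
        for idx in minterms:
            lits = [
                p if (idx >> j) & 1 else f"!{p}"
                for j, p in enumerate(self.parents)
            ]
            terms.append(" & ".join(lits) if len(lits) > 1 else lits[0])
        if len(terms) == 1:
            return terms[0]
        return " | ".join(f"({t})" for t in terms)

    def table_array(self) -> np.ndarray:
        return np.asarray(self.table, dtype=np.uint8)

    def semantically_equal(self, other: "BooleanRule") -> bool:
        """Equality as functions of the union of the two parent sets."""
        allp = tuple(dict.fromkeys(self.parents + other.parents))
        for idx in range(1 << len(allp)):
            env = {p: (idx >> j) & 1 for j, p in enumerate(allp)}
            if self.evaluate(env) != other.evaluate(env):
                return False
        return True
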