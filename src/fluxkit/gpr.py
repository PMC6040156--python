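"""Gene-protein-reaction (GPR) rules.

A GPR is a boolean expression over gene identifiers that states which gene
products are required for a reaction to carry flux: ``and`` means all members
of a complex are needed, ``or`` means isoenzymes substitute for one another.
The empty rule is a distinguished always-active value (spontaneous reactions
and reactions with unknown genetics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import ClassVar, FrozenSet, Iterable, Tuple

__all__ = ["GprExpression", "GprParseError", "parse_gpr", "evaluate_gpr"]


class GprParseError(ValueError):
    """Malformed GPR string; carries the character position of the defect."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class GprExpression:
    """Immutable boolean tree over gene ids.

    ``op`` is one of ``"gene"`` (leaf, ``gene`` set), ``"and"``, ``"or"``
    (``children`` set), or ``"true"`` (the always-active empty rule).
    """

    op: str
    gene: str | None = None
    children: Tuple["GprExpression", ...] = field(default_factory=tuple)

    ALWAYS_ACTIVE: ClassVar["GprExpression"]  # set after class definition

    @property
    def is_always_active(self) -> bool:
        return self.op == "true"

    def genes(self) -> FrozenSet[str]:
        """The set of gene ids appearing as leaves."""
        if self.op == "gene":
            return frozenset({self.gene})
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return frozenset(out)

    def evaluate(self, absent_genes: Iterable[str]) -> bool:
        """Truth value with the given genes knocked out (absent)."""
        absent = set(absent_genes)
        return _eval(self, absent)

    def to_string(self) -> str:
        """Canonical string form, parseable by :func:`parse_gpr`."""
        if self.op == "true":
            return ""
        if self.op == "gene":
            return self.gene  # type: ignore[return-value]
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            s = c.to_string()
            # parenthesize an OR nested under an AND to preserve precedence
            if self.op == "and" and c.op == "or":
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string() or "<always active>"


GprExpression.ALWAYS_ACTIVE = GprExpression(op="true")


def _eval(node: GprExpression, absent: set[str]) -> bool:
    if node.op == "true":
        return True
    if node.op == "gene":
        return node.gene not in absent
    if node.op == "and":
        return all(_eval(c, absent) for c in node.children)
    return any(_eval(c, absent) for c in node.children)


def evaluate_gpr(gpr: GprExpression, absent_genes: Iterable[str]) -> bool:
    """Evaluate a GPR with ``absent_genes`` knocked out.

    AND is conjunction and OR is disjunction over gene presence; the
    always-active rule returns True regardless of knockouts.
    """
    return gpr.evaluate(absent_genes)


# --- parsing -------------------------------------------------------------

_KEYWORDS = {"and", "or"}


def _tokenize(rule: str) -> list[tuple[str, str, int]]:
    """Yield (kind, text, position) with kind in {'(', ')', 'and', 'or', 'id'}."""
    tokens: list[tuple[str, str, int]] = []
    i, n = 0, len(rule)
    while i < n:
        ch = rule[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            tokens.append((ch, ch, i))
            i += 1
            continue
        j = i
        while j < n and not rule[j].isspace() and rule[j] not in "()":
            j += 1
        word = rule[i:j]
        low = word.lower()
        if low in _KEYWORDS:
            tokens.append((low, word, i))
        else:
            tokens.append(("id", word, i))
        i = j
    return tokens


class _Parser:
    """Recursive-descent parser; 'and' binds tighter than 'or'."""

    def __init__(self, rule: str):
        self.rule = rule
        self.tokens = _tokenize(rule)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> GprExpression:
        expr = self.parse_or()
        tok = self.peek()
        if tok is not None:
            raise GprParseError(f"unexpected token {tok[1]!r}", tok[2])
        return expr

    def parse_or(self) -> GprExpression:
        terms = [self.parse_and()]
        while (tok := self.peek()) is not None and tok[0] == "or":
            self.next()
            terms.append(self.parse_and())
        if len(terms) == 1:
            return terms[0]
        return GprExpression(op="or", children=tuple(terms))

    def parse_and(self) -> GprExpression:
        factors = [self.parse_atom()]
        while (tok := self.peek()) is not None and tok[0] == "and":
            self.next()
            factors.append(self.parse_atom())
        if len(factors) == 1:
            return factors[0]
        return GprExpression(op="and", children=tuple(factors))

    def parse_atom(self) -> GprExpression:
        tok = self.next()
        if tok is None:
            raise GprParseError("dangling operator or empty group", len(self.rule))
        kind, text, pos = tok
        if kind == "(":
            inner = self.parse_or()
            closing = self.next()
            if closing is None or closing[0] != ")":
                raise GprParseError("unbalanced parentheses", pos)
            return inner
        if kind == "id":
            return GprExpression(op="gene", gene=text)
        raise GprParseError(f"unexpected token {text!r}", pos)


def parse_gpr(rule: str) -> GprExpression:
    """Parse a GPR rule string into a boolean tree.

    Keywords ``and``/``or`` are case-insensitive, parentheses group, and
    ``and`` binds tighter than ``or``. A blank rule parses to the
    always-active expression.
    """
    if rule is None or not rule.strip():
        return GprExpression.ALWAYS_ACTIVE
    return _Parser(rule).parse()
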