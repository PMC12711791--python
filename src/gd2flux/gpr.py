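"""Gene-protein-reaction (GPR) rule parsing and evaluation.

GPR rules are boolean formulas over gene symbols describing how enzymes
assemble into a reaction's catalytic capability: ``and`` joins obligate
subunits of a complex, ``or`` joins interchangeable isoenzymes.  For
activity scoring the boolean semantics become arithmetic:

* ``and`` -> minimum of the operand activities (a complex is limited by its
  scarcest subunit);
* ``or``  -> sum of the operand activities (isoenzymes contribute
  additively).

``and`` binds tighter than ``or``; parentheses override.  Keywords are
case-insensitive; gene symbols are matched case-sensitively after
whitespace trimming.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Union

import numpy as np

from .errors import ConfigurationError, GprParseError

__all__ = ["Gene", "Op", "GprRule", "parse_gpr", "eval_gpr"]


@dataclass(frozen=True)
class Gene:
    symbol: str


@dataclass(frozen=True)
class Op:
    """Internal node: ``kind`` is "and" or "or"; always >= 2 children."""

    kind: str
    children: tuple["Node", ...]


Node = Union[Gene, Op]


@dataclass
class GprRule:
    """Parsed GPR rule for one reaction."""

    reaction_id: str
    root: Node | None  # None encodes the empty rule (no genes)
    text: str = ""

    def genes(self) -> frozenset[str]:
        if self.root is None:
            return frozenset()
        out: set[str] = set()
        stack: list[Node] = [self.root]
        while stack:
            n = stack.pop()
            if isinstance(n, Gene):
                out.add(n.symbol)
            else:
                stack.extend(n.children)
        return frozenset(out)


_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(rule_text: str, reaction_id: str = "") -> GprRule:
    """Parse a GPR rule string into an expression tree.

    Empty or whitespace-only text yields a rule with ``root=None`` (a
    reaction with no gene association).  Raises :class:`GprParseError`
    with a character offset on malformed input.
    """
    tokens = _tokenize(rule_text)
    if not tokens:
        return GprRule(reaction_id, None, rule_text)
    pos = 0

    def peek() -> tuple[str, int] | None:
        return tokens[pos] if pos < len(tokens) else None

    def parse_or() -> Node:
        nonlocal pos
        children = [parse_and()]
        while (t := peek()) is not None and t[0].lower() == "or":
            pos += 1
            children.append(parse_and())
        return children[0] if len(children) == 1 else Op("or", tuple(children))

    def parse_and() -> Node:
        nonlocal pos
        children = [parse_atom()]
        while (t := peek()) is not None and t[0].lower() == "and":
            pos += 1
            children.append(parse_atom())
        return children[0] if len(children) == 1 else Op("and", tuple(children))

    def parse_atom() -> Node:
        nonlocal pos
        t = peek()
        if t is None:
            raise GprParseError("unexpected end of rule", len(rule_text))
        tok, off = t
        if tok == "(":
            pos += 1
            inner = parse_or()
            t2 = peek()
            if t2 is None or t2[0] != ")":
                raise GprParseError("unbalanced parentheses", off)
            pos += 1
            return inner
        if tok == ")":
            raise GprParseError("unexpected ')'", off)
        if tok.lower() in ("and", "or"):
            raise GprParseError(f"operator {tok!r} where a gene was expected", off)
        pos += 1
        return Gene(tok.strip())

    root = parse_or()
    if pos != len(tokens):
        raise GprParseError(f"trailing token {tokens[pos][0]!r}", tokens[pos][1])
    return GprRule(reaction_id, root, rule_text)


_warned_missing: set[str] = set()


def eval_gpr(
    rule: GprRule,
    expression: Mapping[str, float],
    missing_policy: str = "zero",
) -> float:
    """Evaluate a GPR rule on one sample's per-gene expression values.

    AND nodes take the minimum of their children, OR nodes the sum.  Genes
    absent from ``expression`` contribute 0 under the default ``"zero"``
    policy (sum-neutral for OR, dominating for AND) with one warning per
    gene; ``missing_policy="strict"`` raises instead.  The empty rule
    evaluates to 0.
    """
    if rule.root is None:
        return 0.0

    def rec(node: Node) -> float:
        if isinstance(node, Gene):
            if node.symbol in expression:
                return float(expression[node.symbol])
            if missing_policy == "strict":
                raise ConfigurationError(
                    f"gene {node.symbol!r} missing from expression data "
                    f"(rule {rule.reaction_id or rule.text!r})"
                )
            if node.symbol not in _warned_missing:
                _warned_missing.add(node.symbol)
                warnings.warn(f"gene {node.symbol!r} missing; treated as 0")
            return 0.0
        vals = [rec(c) for c in node.children]
        return min(vals) if node.kind == "and" else float(np.sum(vals))

    return rec(rule.root)


def eval_gpr_matrix(
    rule: GprRule,
    expression,
    missing_policy: str = "zero",
):
    """Vectorized evaluation across samples.

    ``expression`` is a pandas DataFrame (samples x genes); returns a numpy
    vector of per-sample activities in row order.
    """
    import pandas as pd  # local import keeps module import light

    n = len(expression)
    if rule.root is None:
        return np.zeros(n)

    def rec(node: Node) -> np.ndarray:
        if isinstance(node, Gene):
            if node.symbol in expression.columns:
                return expression[node.symbol].to_numpy(dtype=float)
            if missing_policy == "strict":
                raise ConfigurationError(
                    f"gene {node.symbol!r} missing from expression data "
                    f"(rule {rule.reaction_id or rule.text!r})"
                )
            if node.symbol not in _warned_missing:
                _warned_missing.add(node.symbol)
                warnings.warn(f"gene {node.symbol!r} missing; treated as 0")
            return np.zeros(n)
        stacked = np.vstack([rec(c) for c in node.children])
        return stacked.min(axis=0) if node.kind == "and" else stacked.sum(axis=0)

    return rec(rule.root)
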