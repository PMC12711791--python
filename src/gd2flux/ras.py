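"""Reaction Activity Scores (RAS).

A RAS maps one sample's gene expression onto one reaction through the
reaction's GPR rule (AND -> min over subunits, OR -> sum over isoenzymes),
yielding a proxy for enzymatic activity.  Computed over a whole expression
matrix this gives a samples x reactions activity matrix whose column order
follows the graph's deterministic (reaction-ID-sorted) edge order.

The sklearn-style :class:`RasTransformer` wraps the computation, optionally
chaining the transition-probability adjustments from
:mod:`gd2flux.topology` (variants ``rasTP`` and ``rasTPrec``).
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigurationError
from .gpr import GprRule, eval_gpr_matrix, parse_gpr
from .graph import MetabolicGraph

__all__ = ["compute_ras", "RasTransformer", "parse_gpr_table"]


def parse_gpr_table(rules: Mapping[str, str]) -> dict[str, GprRule]:
    """Parse a ``reaction_id -> rule text`` mapping into GprRule objects."""
    return {rid: parse_gpr(text, rid) for rid, text in rules.items()}


def compute_ras(
    graph: MetabolicGraph,
    gprs: Mapping[str, GprRule],
    expression: pd.DataFrame,
    missing_policy: str = "zero",
) -> pd.DataFrame:
    """Evaluate every reaction's GPR on every sample.

    Parameters
    ----------
    graph
        The metabolic graph; its sorted edge order fixes the column order.
    gprs
        ``reaction_id -> GprRule``.  Every key must name a graph reaction.
        Graph reactions without a rule (or with an empty rule) get constant
        RAS 0 with a warning, keeping the matrix dense.
    expression
        Samples x genes DataFrame of normalized, log10-transformed values.

    Returns
    -------
    Samples x reactions DataFrame (variant ``ras``), all values >= 0 when
    the expression input is non-negative.
    """
    reaction_ids = graph.reaction_ids()
    present = set(reaction_ids)
    orphans = [rid for rid in gprs if rid not in present]
    if orphans:
        raise ConfigurationError(f"GPR rules for reactions absent from graph: {orphans}")
    cols = {}
    for rid in reaction_ids:
        rule = gprs.get(rid)
        if rule is None or rule.root is None:
            warnings.warn(f"reaction {rid!r} has no GPR; RAS set to 0")
            cols[rid] = np.zeros(len(expression))
        else:
            cols[rid] = eval_gpr_matrix(rule, expression, missing_policy)
    return pd.DataFrame(cols, index=expression.index, columns=reaction_ids)


class RasTransformer(TransformerMixin, BaseEstimator):
    """Expression matrix -> reaction activity matrix transformer.

    Parameters
    ----------
    graph : MetabolicGraph
    gprs : mapping reaction_id -> GprRule (or rule text)
    variant : {"ras", "rasTP", "rasTPrec"}
        Plain RAS, transition-probability-adjusted RAS, or recursively
        adjusted RAS (see :mod:`gd2flux.topology`).
    missing_policy : {"zero", "strict"}
        Handling of genes referenced by a rule but absent from the data.

    The transformer is stateless aside from its configuration; ``fit`` only
    validates the rule/graph pairing.
    """

    def __init__(self, graph: MetabolicGraph, gprs: Mapping[str, GprRule],
                 variant: str = "ras", missing_policy: str = "zero"):
        self.graph = graph
        self.gprs = gprs
        self.variant = variant
        self.missing_policy = missing_policy

    def _rules(self) -> dict[str, GprRule]:
        return {
            rid: (rule if isinstance(rule, GprRule) else parse_gpr(rule, rid))
            for rid, rule in self.gprs.items()
        }

    def fit(self, X=None, y=None):
        if self.variant not in ("ras", "rasTP", "rasTPrec"):
            raise ConfigurationError(f"unknown RAS variant {self.variant!r}")
        self.rules_ = self._rules()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        from .topology import adjust_matrix  # deferred: circular import

        if not hasattr(self, "rules_"):
            self.fit()
        ras = compute_ras(self.graph, self.rules_, X, self.missing_policy)
        if self.variant == "ras":
            return ras
        return adjust_matrix(self.graph, ras, method="tp" if self.variant == "rasTP" else "tprec")

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.graph.reaction_ids(), dtype=object)
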