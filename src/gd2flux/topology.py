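"""Transition-probability adjustment of reaction activity.

Enzymes in the ganglioside pathway are promiscuous: one enzyme's activity
feeds several competing reactions leaving the same metabolite.  To partition
that activity, each sample's RAS row induces per-edge transition
probabilities

    P_e = r_e / sum(r_e' for e' leaving the same source node),

and the adjusted weight is ``r_e^TP = r_e * P_e``.  On linear stretches
(sole outgoing edge at every step, as along the 0-, a-, b-, and c-series)
P_e is structurally 1 and the adjustment is a no-op; the *recursive*
variant therefore replaces each structural P_e = 1 by the nearest upstream
transition probability that is not 1, walking the unique predecessor chain
back toward the branching node, so branch-point competition propagates down
the series:

    r_e^TPrec = r_e * P~_e.

Both adjustments are per-sample and scale-invariant in the RAS row.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, CycleError
from .graph import MetabolicGraph

__all__ = [
    "transition_probabilities",
    "recursive_tp",
    "adjust_tp",
    "adjust_recursive",
    "adjust_matrix",
]


def _check_coverage(graph: MetabolicGraph, ras_row: Mapping[str, float]) -> None:
    missing = [rid for rid in graph.reaction_ids() if rid not in ras_row]
    if missing:
        raise ConfigurationError(f"RAS row missing reactions: {missing}")


def transition_probabilities(
    graph: MetabolicGraph, ras_row: Mapping[str, float]
) -> pd.Series:
    """Per-edge transition probabilities for one sample.

    For each node, outgoing-edge probabilities are the edge RAS divided by
    the summed outgoing RAS.  A node whose outgoing RAS sums to 0 gets
    probability 0 on all its edges (the adjusted weight is 0 regardless, so
    this avoids 0/0 without changing any result).
    """
    _check_coverage(graph, ras_row)
    probs: dict[str, float] = {}
    for node in graph.nodes:
        out = graph.out_edges(node)
        if not out:
            continue
        values = np.array([float(ras_row[e.reaction_id]) for e in out])
        if (values < 0).any():
            raise ConfigurationError(f"negative RAS on edges leaving {node!r}")
        total = values.sum()
        for e, v in zip(out, values):
            probs[e.reaction_id] = v / total if total > 0 else 0.0
    return pd.Series(probs).reindex(graph.reaction_ids())


def recursive_tp(
    graph: MetabolicGraph, tp_row: Mapping[str, float]
) -> pd.Series:
    """Recursively adjusted transition probabilities P~ for one sample.

    Only edges whose P_e = 1 *structurally* (sole outgoing edge of their
    source, with positive activity) are rewritten; a multi-edge node that
    happens to concentrate all RAS on one edge keeps its P_e.  The walk
    follows unique predecessors upstream and adopts the first transition
    probability != 1; it yields 1 when the chain starts at a source node
    with no non-unit TP above, falls back to P_e (with a warning) when a
    node with several incoming edges is met, and raises on a cycle.
    """
    edges = graph.edges()
    sole = {e.reaction_id: len(graph.out_edges(e.source)) == 1 for e in edges}
    incoming = {n: graph.in_edges(n) for n in graph.nodes}
    out = {}
    for e in edges:
        pe = float(tp_row[e.reaction_id])
        if not (sole[e.reaction_id] and pe == 1.0):
            out[e.reaction_id] = pe
            continue
        # walk upstream from the edge's source along unique predecessors
        node = e.source
        visited = {e.source}
        value = 1.0  # source-rooted pure chain keeps P~ = 1
        while True:
            preds = incoming[node]
            if len(preds) == 0:
                break
            if len(preds) > 1:
                warnings.warn(
                    f"recursive TP walk from {e.reaction_id!r} hit node "
                    f"{node!r} with multiple incoming edges; keeping P_e"
                )
                value = pe
                break
            up = preds[0]
            p_up = float(tp_row[up.reaction_id])
            if p_up != 1.0:
                value = p_up
                break
            if up.source in visited:
                raise CycleError(
                    f"cycle through {up.source!r} during recursive TP walk "
                    f"from edge {e.reaction_id!r}"
                )
            visited.add(up.source)
            node = up.source
        out[e.reaction_id] = value
    return pd.Series(out).reindex(graph.reaction_ids())


def adjust_tp(ras_row: pd.Series, tp_row: pd.Series) -> pd.Series:
    """Variant ``rasTP``: elementwise ``r_e * P_e``."""
    return ras_row * tp_row.reindex(ras_row.index)


def adjust_recursive(ras_row: pd.Series, recursive_row: pd.Series) -> pd.Series:
    """Variant ``rasTPrec``: elementwise ``r_e * P~_e``."""
    return ras_row * recursive_row.reindex(ras_row.index)


def adjust_matrix(
    graph: MetabolicGraph, ras: pd.DataFrame, method: str = "tp"
) -> pd.DataFrame:
    """Apply the TP (``method="tp"``) or recursive (``"tprec"``) adjustment
    to every row of a samples x reactions RAS matrix independently."""
    if method not in ("tp", "tprec"):
        raise ConfigurationError(f"unknown adjustment method {method!r}")
    rows = []
    for _, row in ras.iterrows():
        tp = transition_probabilities(graph, row)
        if method == "tprec":
            tp = recursive_tp(graph, tp)
        rows.append((row * tp.reindex(row.index)).to_numpy())
    return pd.DataFrame(np.vstack(rows) if rows else np.empty((0, ras.shape[1])),
                        index=ras.index, columns=ras.columns)
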