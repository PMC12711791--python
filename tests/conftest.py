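"""Shared fixtures: the ganglio-series toy study, generated at test time."""

import numpy as np
import pandas as pd
import pytest

import gd2flux as g


@pytest.fixture(scope="session")
def ganglio():
    """(graph, gprs, r1) ganglio-series fixture."""
    return g.ganglio_fixture_graph()


@pytest.fixture(scope="session")
def cohort(ganglio):
    """Simulated 50/50 NB-like vs NT-like cohort at the default study
    conditions (effect 4, noise 0.3, seed 7), with derived matrices."""
    graph, gprs, r1 = ganglio
    spec = g.FixtureSpec(seed=7)
    counts, labels = g.simulate_counts(spec, graph, gprs)
    norm = g.FrozenMedianOfRatios().fit(counts.T)
    expr = g.log_transform(norm.transform(counts.T))
    ras = g.compute_ras(graph, gprs, expr)
    return {
        "counts": counts,
        "labels": labels,
        "normalizer": norm,
        "expr": expr,
        "ras": ras,
        "rasTP": g.adjust_matrix(graph, ras, "tp"),
        "rasTPrec": g.adjust_matrix(graph, ras, "tprec"),
    }


@pytest.fixture()
def chain_graph():
    """Minimal 3-node chain A -> B -> C."""
    definition = {
        "metabolites": [{"id": n, "name": n} for n in "ABC"],
        "reactions": [
            {"id": "Rab", "source": "A", "target": "B", "gpr": "G1", "genes": ["G1"]},
            {"id": "Rbc", "source": "B", "target": "C", "gpr": "G2", "genes": ["G2"]},
        ],
    }
    return g.build_graph(definition)


def random_dag(rng: np.random.Generator, n_nodes: int = 8, p_edge: float = 0.4):
    """Random DAG over a topological node order; reaction IDs R000.."""
    nodes = [f"N{i}" for i in range(n_nodes)]
    reactions = []
    k = 0
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                reactions.append({"id": f"R{k:03d}", "source": nodes[i],
                                  "target": nodes[j], "gpr": "", "genes": []})
                k += 1
    if not reactions:  # guarantee at least one edge
        reactions.append({"id": "R000", "source": nodes[0], "target": nodes[1],
                          "gpr": "", "genes": []})
    definition = {"metabolites": [{"id": n, "name": n} for n in nodes],
                  "reactions": reactions}
    return g.build_graph(definition)
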