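"""Metabolite-centric reaction graph.

The glycosphingolipid biosynthesis network is represented as a directed
graph whose nodes are metabolites (KEGG compound IDs or free-form names)
and whose edges are enzymatic reactions.  Each edge carries the reaction ID,
the gene-protein-reaction (GPR) boolean rule, and the gene list.  Parallel
edges between the same metabolite pair are allowed as long as their reaction
IDs differ (distinct enzymatic routes).

Degradation reactions that are not competing biosynthetic steps (e.g. the
GM1->GM2 and GM2->GM3 catabolic reactions) are excluded at construction so
that transition probabilities only partition flux among forward branches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

from .errors import ConfigurationError, GraphStructureError

__all__ = ["Edge", "MetabolicGraph", "ReactionSet", "build_graph"]


@dataclass(frozen=True)
class Edge:
    """One directed reaction edge: ``source`` metabolite -> ``target``."""

    source: str
    target: str
    reaction_id: str
    gpr: str = ""
    genes: tuple[str, ...] = ()

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.reaction_id)


class MetabolicGraph:
    """Directed metabolite graph with reaction-labelled edges.

    Thin wrapper over :class:`networkx.MultiDiGraph` that enforces the
    structural invariants (declared endpoints, unique reaction IDs per node
    pair) and provides the deterministic, reaction-ID-sorted edge orderings
    that every downstream computation relies on.
    """

    def __init__(self, edges: Iterable[Edge] = (), isolated_nodes: Iterable[str] = ()):
        self._g = nx.MultiDiGraph()
        for n in isolated_nodes:
            self._g.add_node(n)
        for e in edges:
            self.add_edge(e)

    # -- construction -------------------------------------------------

    def add_edge(self, edge: Edge) -> None:
        if self._g.has_edge(edge.source, edge.target, key=edge.reaction_id):
            raise GraphStructureError(
                f"duplicate reaction {edge.reaction_id!r} between "
                f"{edge.source!r} and {edge.target!r}"
            )
        self._g.add_edge(
            edge.source,
            edge.target,
            key=edge.reaction_id,
            gpr=edge.gpr,
            genes=tuple(edge.genes),
        )

    # -- queries -------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return sorted(self._g.nodes)

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def edges(self) -> list[Edge]:
        """All edges, sorted lexicographically by reaction ID."""
        return sorted(self._iter_edges(), key=lambda e: (e.reaction_id, e.source, e.target))

    def _iter_edges(self) -> Iterator[Edge]:
        for u, v, k, data in self._g.edges(keys=True, data=True):
            yield Edge(u, v, k, data.get("gpr", ""), tuple(data.get("genes", ())))

    def reaction_ids(self) -> list[str]:
        return [e.reaction_id for e in self.edges()]

    def has_reaction(self, reaction_id: str) -> bool:
        return any(e.reaction_id == reaction_id for e in self._iter_edges())

    def out_edges(self, node: str) -> list[Edge]:
        """Outgoing edges of ``node`` sorted by reaction ID.

        The sorted order makes any order-dependent computation (transition
        probabilities, matrix column layout) reproducible.
        """
        if node not in self._g:
            raise KeyError(f"unknown metabolite node {node!r}")
        out = [
            Edge(u, v, k, d.get("gpr", ""), tuple(d.get("genes", ())))
            for u, v, k, d in self._g.out_edges(node, keys=True, data=True)
        ]
        return sorted(out, key=lambda e: e.reaction_id)

    def in_edges(self, node: str) -> list[Edge]:
        if node not in self._g:
            raise KeyError(f"unknown metabolite node {node!r}")
        inc = [
            Edge(u, v, k, d.get("gpr", ""), tuple(d.get("genes", ())))
            for u, v, k, d in self._g.in_edges(node, keys=True, data=True)
        ]
        return sorted(inc, key=lambda e: e.reaction_id)

    def out_degree(self, node: str) -> int:
        return len(self.out_edges(node))

    def genes(self) -> list[str]:
        """Union of all gene symbols appearing on edges, sorted."""
        out: set[str] = set()
        for e in self._iter_edges():
            out.update(e.genes)
        return sorted(out)

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    # -- serialization -------------------------------------------------

    def to_definition(self) -> dict:
        """Declarative pathway document (round-trips through build_graph)."""
        return {
            "metabolites": [{"id": n, "name": n} for n in self.nodes],
            "reactions": [
                {
                    "id": e.reaction_id,
                    "source": e.source,
                    "target": e.target,
                    "gpr": e.gpr,
                    "genes": list(e.genes),
                    "reversible": False,
                }
                for e in self.edges()
            ],
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_definition(), indent=1))

    @classmethod
    def read_json(cls, path: str | Path) -> "MetabolicGraph":
        return build_graph(json.loads(Path(path).read_text()))

    def write_graphml(self, path: str | Path) -> None:
        g = nx.MultiDiGraph()
        for n in self.nodes:
            g.add_node(n, name=n)
        for e in self.edges():
            g.add_edge(e.source, e.target, key=e.reaction_id,
                       reaction_id=e.reaction_id, gpr=e.gpr,
                       genes=";".join(e.genes))
        nx.write_graphml(g, str(path))

    @classmethod
    def read_graphml(cls, path: str | Path) -> "MetabolicGraph":
        g = nx.read_graphml(str(path), force_multigraph=True)
        edges = [
            Edge(
                u,
                v,
                d.get("reaction_id", str(k)),
                d.get("gpr", ""),
                tuple(x for x in d.get("genes", "").split(";") if x),
            )
            for u, v, k, d in g.edges(keys=True, data=True)
        ]
        return cls(edges, isolated_nodes=(n for n in g.nodes if g.degree(n) == 0))


def build_graph(
    pathway_definition: Mapping,
    excluded_reactions: Sequence[str] = (),
) -> MetabolicGraph:
    """Build a :class:`MetabolicGraph` from a declarative pathway document.

    Parameters
    ----------
    pathway_definition
        Mapping with keys ``metabolites`` (list of ``{"id", "name"}``) and
        ``reactions`` (list of ``{"id", "source", "target", "gpr", "genes",
        "reversible"}``).  Reversible reactions are expanded into two
        directed edges with ``_f``/``_r`` suffixes, since transition
        probabilities are defined on directed edges only.
    excluded_reactions
        Reaction IDs to drop (e.g. degradation reactions that do not compete
        with biosynthesis).  IDs listed here simply never become edges.

    Raises
    ------
    GraphStructureError
        If a reaction references an undeclared metabolite or duplicates a
        reaction ID on the same node pair.
    """
    metabolites = {m["id"] for m in pathway_definition.get("metabolites", [])}
    excluded = set(excluded_reactions)
    edges: list[Edge] = []
    for rxn in pathway_definition.get("reactions", []):
        rid = rxn["id"]
        if rid in excluded:
            continue
        src, tgt = rxn["source"], rxn["target"]
        for endpoint in (src, tgt):
            if endpoint not in metabolites:
                raise GraphStructureError(
                    f"reaction {rid!r} references undeclared metabolite {endpoint!r}"
                )
        gpr = rxn.get("gpr", "")
        genes = tuple(rxn.get("genes", ()))
        if rxn.get("reversible", False):
            edges.append(Edge(src, tgt, rid + "_f", gpr, genes))
            edges.append(Edge(tgt, src, rid + "_r", gpr, genes))
        else:
            edges.append(Edge(src, tgt, rid, gpr, genes))
    used = {e.source for e in edges} | {e.target for e in edges}
    graph = MetabolicGraph(edges, isolated_nodes=metabolites - used)
    return graph


@dataclass
class ReactionSet:
    """Named promoting/mitigating reaction split used as SVM features.

    ``promoting`` reactions produce GD2 or its direct precursor; ``mitigating``
    reactions consume GD2 or divert its precursors into sibling series.
    """

    name: str
    promoting: list[str] = field(default_factory=list)
    mitigating: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.promoting) & set(self.mitigating)
        if overlap:
            raise ConfigurationError(
                f"reaction set {self.name!r}: promoting and mitigating sets "
                f"overlap on {sorted(overlap)}"
            )

    def validate(self, graph: MetabolicGraph) -> None:
        """Raise ConfigurationError if any member is absent from ``graph``."""
        present = set(graph.reaction_ids())
        missing = [r for r in [*self.promoting, *self.mitigating] if r not in present]
        if missing:
            raise ConfigurationError(
                f"reaction set {self.name!r}: reactions not in graph: {missing}"
            )

    def to_dict(self) -> dict:
        return {"name": self.name, "promoting": list(self.promoting),
                "mitigating": list(self.mitigating)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReactionSet":
        return cls(d["name"], list(d["promoting"]), list(d["mitigating"]))
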