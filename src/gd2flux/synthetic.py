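"""Synthetic study fixtures.

Real training data for the GD2 score (a large tumor/normal RNA-seq
compendium plus a licensed KEGG pathway snapshot) cannot be bundled, so
this module generates a self-contained stand-in study:

* :func:`ganglio_fixture_graph` builds the ganglio-series neighborhood of
  GD2 — the branch points at GM3 (a-series vs b-series) and GD3 (GD2 vs
  c-series) plus the linear upstream stem from ceramide — with real KEGG
  reaction IDs and enzyme gene symbols, and the curated promoting/
  mitigating reaction split (``r1``) used as SVM features.
* :func:`simulate_counts` draws RNA-seq-like count matrices from a
  lognormal-Poisson hierarchy in which class 1 ("NB-like") samples have
  elevated expression of GD2-promoting enzymes and class 0 ("NT-like")
  samples elevated GD2-mitigating enzymes.  B4GALNT1 sits on both sides of
  the split (it catalyzes both the promoting GD3->GD2 step and the
  mitigating GM3->GM2 step, mirroring real enzyme promiscuity) and is
  shifted in class 1 only — reproducing the ambiguity the transition-
  probability adjustment is designed to resolve.

The generator aims at ordering structure, not full RNA-seq realism: no
batch effects, no gene-gene correlation beyond the class shifts, no
negative-binomial dispersion tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .gpr import GprRule, parse_gpr
from .graph import MetabolicGraph, ReactionSet, build_graph

__all__ = [
    "FixtureSpec", "ganglio_definition", "ganglio_fixture_graph",
    "DEGRADATION_REACTIONS", "simulate_counts",
]

#: Catabolic reactions present in the pathway source but excluded from the
#: graph: they run against biosynthesis and are not competing branches.
DEGRADATION_REACTIONS = ("R06010", "R06004")

_GANGLIO_REACTIONS = [
    # (reaction_id, source, target, gpr)
    ("R01496", "Cer", "GlcCer", "UGCG"),
    ("R01281", "GlcCer", "LacCer", "B4GALT5 or B4GALT6"),
    ("R05937", "LacCer", "GM3", "ST3GAL5"),
    ("R05939", "GM3", "GM2", "B4GALNT1"),          # a-series (mitigating)
    ("R05940", "GM3", "GD3", "ST8SIA1"),           # b-series entry (promoting)
    ("R05946", "GD3", "GD2", "B4GALNT1"),          # GD2 synthesis (promoting)
    ("R05948", "GD3", "GT3", "ST8SIA3"),           # c-series entry (mitigating)
    ("R05947", "GD2", "GD1b", "B3GALT4"),          # GD2 consumption (mitigating)
    ("R05941", "GM2", "GM1", "B3GALT4"),           # a-series elongation (mitigating)
    # degradation reactions, excluded at build time
    ("R06010", "GM1", "GM2", "GLB1"),
    ("R06004", "GM2", "GM3", "HEXA and HEXB"),
]

R1_PROMOTING = ["R05946", "R05940"]
R1_MITIGATING = ["R05939", "R05948", "R05947", "R05941"]


def ganglio_definition() -> dict:
    """Declarative pathway document for the ganglio-series fixture.

    Includes the two degradation reactions so exclusion at build time is
    exercised, and declares its expected post-exclusion node/edge counts.
    """
    nodes = sorted({m for _, s, t, _ in _GANGLIO_REACTIONS for m in (s, t)})
    return {
        "metabolites": [{"id": n, "name": n} for n in nodes],
        "reactions": [
            {
                "id": rid, "source": src, "target": tgt, "gpr": gpr,
                "genes": sorted(parse_gpr(gpr).genes()), "reversible": False,
            }
            for rid, src, tgt, gpr in _GANGLIO_REACTIONS
        ],
        "declared_counts": {
            "nodes": len(nodes),
            "edges": len(_GANGLIO_REACTIONS) - len(DEGRADATION_REACTIONS),
        },
    }


def ganglio_fixture_graph() -> tuple[MetabolicGraph, dict[str, GprRule], ReactionSet]:
    """Deterministic fixture graph, its GPR rules, and the r1 reaction set."""
    graph = build_graph(ganglio_definition(), excluded_reactions=DEGRADATION_REACTIONS)
    gprs = {
        rid: parse_gpr(gpr, rid)
        for rid, _, _, gpr in _GANGLIO_REACTIONS
        if rid not in DEGRADATION_REACTIONS
    }
    r1 = ReactionSet("r1", list(R1_PROMOTING), list(R1_MITIGATING))
    r1.validate(graph)
    return graph, gprs, r1


@dataclass
class FixtureSpec:
    """Study conditions for the synthetic cohort.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 50 samples per class, a 4-fold shift of the class-defining
    enzyme transcripts, lognormal dispersion 0.3, and libraries of
    200k-400k fragments over ~100 genes.
    """

    n_class1: int = 50
    n_class0: int = 50
    effect_size: float = 4.0
    noise_sd: float = 0.3
    library_size: tuple[int, int] = (200_000, 400_000)
    n_background_genes: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_class1 < 1 or self.n_class0 < 1:
            raise InputError("sample counts must be >= 1")
        if self.effect_size < 1:
            raise InputError("effect_size must be >= 1")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")


def pathway_gene_split(gprs: dict[str, GprRule]) -> tuple[set[str], set[str]]:
    """Promoting vs mitigating gene sets derived from the r1 reaction GPRs.

    Genes appearing on both sides (enzyme promiscuity) are treated as
    promoting-only for the simulation shift: they move in class 1.
    """
    promoting = set().union(*(gprs[r].genes() for r in R1_PROMOTING if r in gprs))
    mitigating = set().union(*(gprs[r].genes() for r in R1_MITIGATING if r in gprs))
    return promoting, mitigating - promoting


def simulate_counts(
    spec: FixtureSpec,
    graph: MetabolicGraph,
    gprs: dict[str, GprRule],
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw a synthetic count matrix and class labels.

    A gene's baseline relative abundance is lognormal across genes; each
    sample multiplies it by a lognormal noise factor (sd ``noise_sd``) and,
    for the class-defining genes, by ``effect_size``; counts are Poisson
    at the sample's library size.  Deterministic under ``spec.seed``.

    Returns
    -------
    counts : genes x samples DataFrame of non-negative integers
        (class-1 samples named ``NB...``, class-0 ``NT...``).
    labels : per-sample 1 (NB-like) / 0 (NT-like) Series.
    """
    rng = np.random.default_rng(spec.seed)
    promoting_genes, mitigating_genes = pathway_gene_split(gprs)
    pathway_genes = graph.genes()
    background = [f"BG{i:03d}" for i in range(spec.n_background_genes)]
    genes = pathway_genes + background
    n_genes = len(genes)

    baseline = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=n_genes)
    prom_idx = np.array([g in promoting_genes for g in genes])
    mit_idx = np.array([g in mitigating_genes for g in genes])

    n = spec.n_class1 + spec.n_class0
    labels = np.r_[np.ones(spec.n_class1, dtype=int), np.zeros(spec.n_class0, dtype=int)]
    sample_ids = [f"NB{i + 1:03d}" for i in range(spec.n_class1)] + \
                 [f"NT{i + 1:03d}" for i in range(spec.n_class0)]

    lo, hi = spec.library_size
    libs = rng.uniform(lo, hi, size=n)
    counts = np.empty((n_genes, n), dtype=np.int64)
    for j in range(n):
        mean = baseline.copy()
        if labels[j] == 1:
            mean[prom_idx] *= spec.effect_size
        else:
            mean[mit_idx] *= spec.effect_size
        mean = mean * rng.lognormal(mean=0.0, sigma=spec.noise_sd, size=n_genes)
        rate = libs[j] * mean / mean.sum()
        counts[:, j] = rng.poisson(rate)

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                             columns=pd.Index(sample_ids, name="sample"))
    return counts_df, pd.Series(labels, index=counts_df.columns, name="label")
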