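"""Copy-number-alteration association screen.

Within each tumor subgroup, genes are screened for association between
their copy-number status (cBioPortal-style integer codes) and the GD2
score, using Kruskal-Wallis across status levels with a Benjamini-Hochberg
adjustment per subgroup and an eta-squared effect-size gate.  This is the
route by which, e.g., B4GALNT1 amplification surfaces as a candidate
biomarker of GD2-positive sarcoma.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import InputError
from .stats import bh_adjust, kruskal_wallis

__all__ = ["CNA_STATUS_LABELS", "integrate", "filter_testable", "screen"]

CNA_STATUS_LABELS = {
    -2: "homozygous deletion",
    -1: "hemizygous deletion",
    0: "no change",
    1: "gain",
    2: "high-level amplification",
}

_VALID_CODES = frozenset(CNA_STATUS_LABELS)


def integrate(
    cna: pd.DataFrame,
    scores: pd.Series,
    subgroups: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Join CNA status with GD2 scores by patient/sample ID.

    Parameters
    ----------
    cna
        Genes x samples matrix of integer codes in {-2..2} (NaN = missing).
    scores
        Per-sample GD2 score indexed by the same IDs.
    subgroups
        Optional per-sample subgroup labels; samples without one fall into
        a single ``"all"`` subgroup.

    Returns
    -------
    Long-format DataFrame with columns ``subgroup, gene, sample, status,
    score`` restricted to the shared samples (inner join).  Raises on an
    empty intersection or duplicated patient IDs in the CNA matrix.
    """
    if cna.columns.duplicated().any():
        dupes = sorted(set(cna.columns[cna.columns.duplicated()]))
        raise InputError(f"duplicate patient IDs in CNA matrix: {dupes}")
    codes = cna.to_numpy(dtype=float)
    bad = ~np.isin(codes[~np.isnan(codes)], list(_VALID_CODES))
    if bad.any():
        raise InputError("CNA codes must be integers in -2..2 (or missing)")
    shared = cna.columns.intersection(scores.index)
    if len(shared) == 0:
        raise InputError("no shared patient IDs between CNA matrix and scores")
    long = (
        cna.loc[:, shared]
        .rename_axis(index="gene", columns="sample")
        .stack(future_stack=True)
        .rename("status")
        .reset_index()
    )
    long["score"] = long["sample"].map(scores)
    if subgroups is not None:
        long["subgroup"] = long["sample"].map(subgroups)
        long = long.dropna(subset=["subgroup"])
    else:
        long["subgroup"] = "all"
    return long[["subgroup", "gene", "sample", "status", "score"]]


def filter_testable(joined: pd.DataFrame, min_per_cell: int = 5) -> pd.DataFrame:
    """Restrict to (subgroup, gene) cells that support a Kruskal-Wallis test.

    Drops records with missing CNA status, then status levels carried by
    fewer than ``min_per_cell`` samples within their subgroup-gene cell,
    then genes left with at most one status level.  Idempotent; may return
    an empty frame.
    """
    if min_per_cell < 1:
        raise InputError("min_per_cell must be >= 1")
    out = joined.dropna(subset=["status"]).copy()
    if out.empty:
        return out
    cell_counts = out.groupby(["subgroup", "gene", "status"])["sample"].transform("size")
    out = out[cell_counts >= min_per_cell]
    if out.empty:
        return out
    n_levels = out.groupby(["subgroup", "gene"])["status"].transform("nunique")
    return out[n_levels > 1].reset_index(drop=True)


def screen(
    testable: pd.DataFrame,
    alpha: float = 0.05,
    eta2_threshold: float = 0.06,
) -> pd.DataFrame:
    """Kruskal-Wallis screen of GD2 score across CNA status per gene.

    BH adjustment is applied within each subgroup across its tested genes.
    A gene is flagged significant iff adjusted p < ``alpha`` AND eta^2 >
    ``eta2_threshold`` (a moderate-or-stronger association).
    """
    if testable.empty:
        raise InputError("no testable subgroup-gene combinations")
    records = []
    for (subgroup, gene), cell in testable.groupby(["subgroup", "gene"]):
        groups = [g["score"].to_numpy() for _, g in cell.groupby("status")]
        kw = kruskal_wallis(groups)
        records.append({
            "subgroup": subgroup, "gene": gene,
            "H": kw["H"], "p": kw["p"], "eta_squared": kw["eta_squared"],
            "n": kw["n"], "n_levels": len(groups),
        })
    table = pd.DataFrame.from_records(records)
    table["p_adj"] = np.nan
    for subgroup, idx in table.groupby("subgroup").groups.items():
        table.loc[idx, "p_adj"] = bh_adjust(table.loc[idx, "p"])
    table["significant"] = (table["p_adj"] < alpha) & (table["eta_squared"] > eta2_threshold)
    return table
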