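"""Frozen median-of-ratios normalization.

Median-of-ratios estimates a per-sample size factor as the median, over
genes, of the sample's counts divided by the gene's geometric mean across
samples.  "Frozen" means the geometric means are fitted once on a training
cohort and reused verbatim for any new dataset, so newly normalized samples
land on the training scale and downstream scores remain comparable across
datasets.

Given training counts :math:`x_{ij}` (gene *i*, sample *j*):

* reference geometric mean  :math:`g_i = (\\prod_j x_{ij})^{1/n}` over
  genes with all-positive training counts ("usable" genes);
* training ratio medians    :math:`m_j = \\mathrm{median}_i\\, x_{ij}/g_i`;
* for a new sample :math:`x^*`: :math:`m^* = \\mathrm{median}_i\\, x^*_i/g_i`
  over shared usable genes, and the frozen size factor
  :math:`s^* = m^* / \\overline{m}` where :math:`\\overline{m}` is the mean
  (optionally the sum) of the training ratio medians.  Dividing by the mean
  makes the average training-sample size factor 1, keeping the training and
  prediction scales identical.

Normalized values are ``counts / s*``, usually followed by
:func:`log_transform` (log10 with pseudocount).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import InputError

__all__ = ["FrozenMedianOfRatios", "log_transform"]


def _as_frame(X) -> pd.DataFrame:
    """Coerce to a samples x genes DataFrame."""
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"g{i}" for i in range(X.shape[1])])


class FrozenMedianOfRatios(TransformerMixin, BaseEstimator):
    """Median-of-ratios size factors with a frozen training reference.

    Parameters
    ----------
    denominator : {"mean", "sum"}
        Statistic of the training ratio medians used as the global
        denominator of ``s*``.  ``"mean"`` (default) makes the average
        training size factor equal 1.

    Attributes
    ----------
    gene_ids_ : pd.Index
        All training gene identifiers.
    usable_genes_ : pd.Index
        Genes with strictly positive counts in every training sample; only
        these enter the reference and the ratio medians.
    reference_geomeans_ : pd.Series
        Per-usable-gene geometric means over the training samples.
    training_ratio_medians_ : pd.Series
        Per-training-sample median ratio ``m_j``.

    Notes
    -----
    Input orientation is scikit-learn style: rows are samples, columns are
    genes (transpose of the genes x samples TSV convention).
    """

    def __init__(self, denominator: str = "mean"):
        self.denominator = denominator

    # -- fitting -------------------------------------------------------

    def fit(self, X, y=None):
        X = _as_frame(X)
        if X.shape[0] < 2:
            raise InputError("frozen normalization needs at least 2 training samples")
        if (X.to_numpy() < 0).any():
            raise InputError("raw counts must be non-negative")
        if X.columns.duplicated().any():
            raise InputError("gene identifiers must be unique")
        usable = (X > 0).all(axis=0)
        if not usable.any():
            raise InputError("no gene has all-positive counts; cannot fit reference")
        self.gene_ids_ = X.columns
        self.usable_genes_ = X.columns[usable]
        logs = np.log(X.loc[:, usable].to_numpy(dtype=float))
        self.reference_geomeans_ = pd.Series(
            np.exp(logs.mean(axis=0)), index=self.usable_genes_
        )
        ratios = X.loc[:, usable].div(self.reference_geomeans_, axis=1)
        self.training_ratio_medians_ = ratios.median(axis=1)
        return self

    def _global_denominator(self) -> float:
        m = self.training_ratio_medians_
        if self.denominator == "mean":
            return float(m.mean())
        if self.denominator == "sum":
            return float(m.sum())
        raise InputError(f"unknown denominator convention {self.denominator!r}")

    # -- prediction-side -----------------------------------------------

    def size_factors(self, X) -> pd.Series:
        """Frozen size factors ``s*`` for new samples (rows of ``X``)."""
        check_is_fitted(self, "reference_geomeans_")
        X = _as_frame(X)
        shared = X.columns.intersection(self.usable_genes_)
        if len(shared) == 0:
            raise InputError("no overlap between new genes and usable reference genes")
        if len(shared) < 0.5 * len(self.usable_genes_):
            warnings.warn(
                f"only {len(shared)}/{len(self.usable_genes_)} usable reference "
                "genes present in the new dataset; size factors may be unstable"
            )
        sub = X.loc[:, shared]
        zero_rows = (sub.to_numpy() == 0).all(axis=1)
        if zero_rows.any():
            bad = list(sub.index[zero_rows])
            raise InputError(f"sample(s) with all-zero shared counts: {bad}")
        m_star = sub.div(self.reference_geomeans_.loc[shared], axis=1).median(axis=1)
        return m_star / self._global_denominator()

    def transform(self, X) -> pd.DataFrame:
        """Normalize counts: each sample divided by its frozen size factor."""
        X = _as_frame(X)
        s = self.size_factors(X)
        return X.div(s, axis=0)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "gene_ids_")
        return np.asarray(self.gene_ids_, dtype=object)

    # -- persistence ---------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        check_is_fitted(self, "reference_geomeans_")
        doc = {
            "schema": "gd2flux.normalizer/1",
            "denominator": self.denominator,
            "gene_ids": list(map(str, self.gene_ids_)),
            "usable_genes": list(map(str, self.usable_genes_)),
            "reference_geomeans": self.reference_geomeans_.to_list(),
            "training_sample_ids": list(map(str, self.training_ratio_medians_.index)),
            "training_ratio_medians": self.training_ratio_medians_.to_list(),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "FrozenMedianOfRatios":
        doc = json.loads(Path(path).read_text())
        if doc.get("schema") != "gd2flux.normalizer/1":
            raise InputError(f"{path}: not a gd2flux normalizer file")
        obj = cls(denominator=doc["denominator"])
        obj.gene_ids_ = pd.Index(doc["gene_ids"])
        obj.usable_genes_ = pd.Index(doc["usable_genes"])
        obj.reference_geomeans_ = pd.Series(
            doc["reference_geomeans"], index=obj.usable_genes_
        )
        obj.training_ratio_medians_ = pd.Series(
            doc["training_ratio_medians"], index=doc["training_sample_ids"]
        )
        return obj


def log_transform(normalized, pseudocount: float = 1.0):
    """log10 transformation with a pseudocount.

    ``value -> log10(value + pseudocount)``.  The default pseudocount of 1
    maps zeros to zeros.  Raises if any ``value + pseudocount <= 0``.
    """
    if pseudocount < 0:
        raise InputError("pseudocount must be >= 0")
    frame = isinstance(normalized, pd.DataFrame) or isinstance(normalized, pd.Series)
    arr = normalized.to_numpy(dtype=float) if frame else np.asarray(normalized, dtype=float)
    if (arr + pseudocount <= 0).any():
        raise InputError("log10 undefined: value + pseudocount <= 0 encountered")
    out = np.log10(arr + pseudocount)
    if isinstance(normalized, pd.DataFrame):
        return pd.DataFrame(out, index=normalized.index, columns=normalized.columns)
    if isinstance(normalized, pd.Series):
        return pd.Series(out, index=normalized.index, name=normalized.name)
    return out
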