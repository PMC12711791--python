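"""GD2 score model.

Two features summarize a sample's ganglioside pathway state: the summed
activity of GD2-promoting reactions and the summed activity of
GD2-mitigating reactions.  A support vector machine trained to separate
neuroblastoma (label 1) from normal tissue (label 0) on these two features
yields, through its decision value (for a linear kernel, the signed
distance from the separating hyperplane), a continuous GD2 score.

:class:`Gd2Svm` follows the scikit-learn estimator contract and stores
everything needed to reproduce decision values exactly: the feature-scaling
constants fitted on training data and, for the linear kernel, the explicit
weight vector ``w`` and intercept ``b`` with ``score(x) = w . scaled(x) + b``.
Models serialize to JSON so that scores are bit-reproducible across
processes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigurationError, InputError
from .graph import ReactionSet

__all__ = ["aggregate_features", "Gd2Svm", "two_gene_signature", "FEATURE_COLUMNS"]

FEATURE_COLUMNS = ("sum_promoting", "sum_mitigating")


def aggregate_features(
    ras_matrix: pd.DataFrame,
    reaction_set: ReactionSet,
    labels: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Sum promoting and mitigating reaction activities per sample.

    Returns a DataFrame with columns ``sum_promoting`` and
    ``sum_mitigating`` (and ``label`` if given).  An empty promoting or
    mitigating list yields a zero column.  Reactions named by the set but
    absent from the matrix raise a configuration error listing them.
    """
    missing = [r for r in [*reaction_set.promoting, *reaction_set.mitigating]
               if r not in ras_matrix.columns]
    if missing:
        raise ConfigurationError(
            f"reaction set {reaction_set.name!r}: reactions missing from "
            f"RAS matrix: {missing}"
        )
    out = pd.DataFrame(index=ras_matrix.index)
    out["sum_promoting"] = (
        ras_matrix[list(reaction_set.promoting)].sum(axis=1)
        if reaction_set.promoting else 0.0
    )
    out["sum_mitigating"] = (
        ras_matrix[list(reaction_set.mitigating)].sum(axis=1)
        if reaction_set.mitigating else 0.0
    )
    if labels is not None:
        out["label"] = pd.Series(labels).reindex(out.index).astype(int)
    return out


def _feature_array(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        cols = [c for c in FEATURE_COLUMNS if c in X.columns]
        if len(cols) == len(FEATURE_COLUMNS):
            X = X[list(FEATURE_COLUMNS)]
        elif "label" in X.columns:
            X = X.drop(columns=["label"])
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


class Gd2Svm(ClassifierMixin, BaseEstimator):
    """SVM over (sum_promoting, sum_mitigating) with decision-value scoring.

    Parameters
    ----------
    kernel : {"linear", "rbf", "polynomial", "sigmoid", "laplacian"}
    C : float
        Soft-margin penalty.
    scaling : {"raw", "scaled", "ranged"}
        Feature preprocessing fitted on training data and frozen: none,
        z-score, or min-max.  Constants are reused verbatim at prediction.
    gamma : "scale" or float
        Kernel coefficient for the non-linear kernels; ``"scale"`` resolves
        to ``1 / (n_features * var(scaled X))`` at fit time.
    degree, coef0 : polynomial / sigmoid kernel parameters.
    class_weight : None or "balanced"
        Off by default: the training contrast is deliberately fitted
        unweighted despite class imbalance.
    random_state : int or None
        Recorded in metadata; the dual solver itself is deterministic.

    Attributes
    ----------
    classes_ : array([0, 1])
    center_, scale_ : fitted scaling constants (identity for "raw").
    coef_, intercept_ : linear-kernel weight vector (in scaled feature
        space) and bias; ``decision_function(x) = coef_ @ scaled(x) + intercept_``.
    n_support_ : total number of support vectors.

    Predicted class is 1 iff the decision value is strictly positive; a
    sample exactly on the hyperplane classifies as 0 (deterministic
    tie-break on a measure-zero event).
    """

    _KERNEL_MAP = {"linear": "linear", "rbf": "rbf", "polynomial": "poly",
                   "sigmoid": "sigmoid", "laplacian": "laplacian"}

    def __init__(self, kernel: str = "linear", C: float = 1.0,
                 scaling: str = "scaled", gamma="scale", degree: int = 3,
                 coef0: float = 0.0, class_weight=None, random_state=None):
        self.kernel = kernel
        self.C = C
        self.scaling = scaling
        self.gamma = gamma
        self.degree = degree
        self.coef0 = coef0
        self.class_weight = class_weight
        self.random_state = random_state

    # -- scaling -------------------------------------------------------

    def _fit_scaling(self, X: np.ndarray) -> None:
        if self.scaling == "raw":
            self.center_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        elif self.scaling == "scaled":
            self.center_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.scale_ = np.where(sd > 0, sd, 1.0)
        elif self.scaling == "ranged":
            lo, hi = X.min(axis=0), X.max(axis=0)
            self.center_ = lo
            rng = hi - lo
            self.scale_ = np.where(rng > 0, rng, 1.0)
        else:
            raise ConfigurationError(f"unknown scaling mode {self.scaling!r}")

    def _scaled(self, X: np.ndarray) -> np.ndarray:
        return (X - self.center_) / self.scale_

    # -- kernels (manual, so saved models reproduce scores exactly) ----

    def _kernel_matrix(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        g = self.gamma_
        if self.kernel == "rbf":
            sq = ((A[:, None, :] - B[None, :, :]) ** 2).sum(-1)
            return np.exp(-g * sq)
        if self.kernel == "polynomial":
            return (g * A @ B.T + self.coef0) ** self.degree
        if self.kernel == "sigmoid":
            return np.tanh(g * A @ B.T + self.coef0)
        if self.kernel == "laplacian":
            l1 = np.abs(A[:, None, :] - B[None, :, :]).sum(-1)
            return np.exp(-g * l1)
        raise ConfigurationError(f"unknown kernel {self.kernel!r}")

    # -- fit / predict -------------------------------------------------

    def fit(self, X, y):
        X = _feature_array(X)
        y = np.asarray(y).astype(int).ravel()
        if not np.isfinite(X).all():
            raise InputError("non-finite feature values")
        classes = np.unique(y)
        if len(classes) < 2:
            raise InputError("training labels contain a single class")
        if not set(classes) <= {0, 1}:
            raise InputError("labels must be binary 0 (NT) / 1 (NB)")
        if self.kernel not in self._KERNEL_MAP:
            raise ConfigurationError(f"unsupported kernel {self.kernel!r}")
        self._fit_scaling(X)
        Xs = self._scaled(X)
        if self.gamma == "scale":
            var = Xs.var()
            self.gamma_ = 1.0 / (X.shape[1] * var) if var > 0 else 1.0
        else:
            self.gamma_ = float(self.gamma)
        sk_kernel = self._KERNEL_MAP[self.kernel]
        svc = SVC(
            kernel="precomputed" if sk_kernel == "laplacian" else sk_kernel,
            C=self.C, gamma=self.gamma_, degree=self.degree, coef0=self.coef0,
            class_weight=self.class_weight,
        )
        if sk_kernel == "laplacian":
            svc.fit(self._kernel_matrix(Xs, Xs), y)
            self.support_vectors_ = Xs[svc.support_]
        else:
            svc.fit(Xs, y)
            self.support_vectors_ = svc.support_vectors_
        self.classes_ = svc.classes_
        self.dual_coef_ = svc.dual_coef_.ravel()
        self.intercept_ = float(svc.intercept_[0])
        self.n_support_ = int(svc.n_support_.sum())
        if self.kernel == "linear":
            self.coef_ = (self.dual_coef_ @ self.support_vectors_).ravel()
        else:
            self.coef_ = None
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        """GD2 scores: SVM decision values on the training scale."""
        check_is_fitted(self, "support_vectors_")
        Xs = self._scaled(_feature_array(X))
        if self.kernel == "linear":
            return Xs @ self.coef_ + self.intercept_
        K = self._kernel_matrix(Xs, self.support_vectors_)
        return K @ self.dual_coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)

    def score_table(self, features: pd.DataFrame,
                    groups: Optional[pd.Series] = None) -> pd.DataFrame:
        """Per-sample score table: GD2 score, predicted class, features."""
        scores = self.decision_function(features)
        out = pd.DataFrame(index=features.index)
        out["gd2_score"] = scores
        out["predicted_class"] = (scores > 0).astype(int)
        for c in FEATURE_COLUMNS:
            if isinstance(features, pd.DataFrame) and c in features.columns:
                out[c] = features[c]
        if groups is not None:
            out["group"] = pd.Series(groups).reindex(out.index)
        return out

    # -- persistence ---------------------------------------------------

    def to_json(self, path: str | Path, metadata: Optional[dict] = None) -> None:
        check_is_fitted(self, "support_vectors_")
        doc = {
            "schema": "gd2flux.model/1",
            "kernel": self.kernel, "C": self.C, "scaling": self.scaling,
            "gamma": self.gamma_, "degree": self.degree, "coef0": self.coef0,
            "center": self.center_.tolist(), "scale": self.scale_.tolist(),
            "support_vectors": self.support_vectors_.tolist(),
            "dual_coef": self.dual_coef_.tolist(),
            "intercept": self.intercept_,
            "coef": None if self.coef_ is None else self.coef_.tolist(),
            "n_support": self.n_support_,
            "metadata": metadata or {},
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "Gd2Svm":
        doc = json.loads(Path(path).read_text())
        if doc.get("schema") != "gd2flux.model/1":
            raise InputError(f"{path}: not a gd2flux model file")
        obj = cls(kernel=doc["kernel"], C=doc["C"], scaling=doc["scaling"],
                  gamma=doc["gamma"], degree=doc["degree"], coef0=doc["coef0"])
        obj.gamma_ = float(doc["gamma"])
        obj.center_ = np.asarray(doc["center"], dtype=float)
        obj.scale_ = np.asarray(doc["scale"], dtype=float)
        obj.support_vectors_ = np.asarray(doc["support_vectors"], dtype=float)
        obj.dual_coef_ = np.asarray(doc["dual_coef"], dtype=float)
        obj.intercept_ = float(doc["intercept"])
        obj.coef_ = None if doc["coef"] is None else np.asarray(doc["coef"], dtype=float)
        obj.n_support_ = int(doc["n_support"])
        obj.classes_ = np.array([0, 1])
        obj.n_features_in_ = obj.support_vectors_.shape[1]
        obj.metadata_ = doc.get("metadata", {})
        return obj


def two_gene_signature(expression: pd.DataFrame) -> pd.Series:
    """Baseline two-gene signature: B4GALNT1 + ST8SIA1 expression.

    ``expression`` is samples x genes, normalized and log10-transformed.
    The sum of the two synthase transcripts is the published gene-level
    comparator for the pathway-informed score.
    """
    for gene in ("B4GALNT1", "ST8SIA1"):
        if gene not in expression.columns:
            raise InputError(f"gene {gene!r} absent from expression matrix")
    return (expression["B4GALNT1"] + expression["ST8SIA1"]).rename("two_gene_signature")
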