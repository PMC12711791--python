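"""Evaluation machinery and group statistics.

Covers the classification metrics used to judge the NB-vs-NT contrast
(balanced accuracy, precision, recall, F1, detection rate/prevalence,
ROC/PR AUCs), the reaction-label permutation test that benchmarks the
curated promoting/mitigating sets against random ones, reaction-set
benchmarking across RAS variants, and the nonparametric group-comparison
statistics (Wilcoxon rank-sum, Cliff's delta, Kruskal-Wallis with eta
squared, Dunn's post hoc test, Benjamini-Hochberg adjustment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn import metrics as skm
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .graph import ReactionSet
from .model import Gd2Svm, aggregate_features

__all__ = [
    "MetricsReport", "classification_metrics", "roc_pr_curves",
    "PermutationResult", "permutation_test", "benchmark_reaction_sets",
    "wilcoxon_rank_sum", "cliffs_delta", "kruskal_wallis", "dunn_posthoc",
    "bh_adjust",
]

PERMUTATION_METRICS = ("balanced_accuracy", "precision", "recall", "f1")


# ---------------------------------------------------------------------------
# classification metrics

@dataclass
class MetricsReport:
    balanced_accuracy: float
    precision: float
    recall: float
    f1: float
    accuracy: float
    specificity: float
    detection_rate: float
    detection_prevalence: float
    roc_auc: Optional[float] = None
    pr_auc: Optional[float] = None
    support_vector_count: Optional[int] = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def classification_metrics(labels, predictions, scores=None) -> MetricsReport:
    """Confusion-matrix metrics with positive class = 1 (NB).

    Balanced accuracy is computed as (recall + specificity)/2 so the
    identity holds exactly.  AUCs need ``scores`` and both classes present;
    otherwise they are reported as ``None``.  Precision/recall/F1 are 0
    when their denominators vanish.
    """
    y = np.asarray(labels).astype(int)
    yhat = np.asarray(predictions).astype(int)
    tp = int(((y == 1) & (yhat == 1)).sum())
    fn = int(((y == 1) & (yhat == 0)).sum())
    fp = int(((y == 0) & (yhat == 1)).sum())
    tn = int(((y == 0) & (yhat == 0)).sum())
    n = len(y)
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    roc_auc = pr_auc = None
    if scores is not None and len(np.unique(y)) == 2:
        scores = np.asarray(scores, dtype=float)
        if np.ptp(scores) == 0:
            warnings.warn("constant scores: ROC AUC reported as 0.5")
            roc_auc = 0.5
        else:
            roc_auc = float(skm.roc_auc_score(y, scores))
        pr_auc = float(skm.average_precision_score(y, scores))
    return MetricsReport(
        balanced_accuracy=(recall + specificity) / 2,
        precision=precision, recall=recall, f1=f1,
        accuracy=(tp + tn) / n if n else 0.0,
        specificity=specificity,
        detection_rate=tp / n if n else 0.0,
        detection_prevalence=(tp + fp) / n if n else 0.0,
        roc_auc=roc_auc, pr_auc=pr_auc,
    )


def roc_pr_curves(labels, scores) -> dict:
    """ROC and precision-recall curves with AUCs.

    ROC comes from the threshold sweep over unique scores; the PR area uses
    the step-interpolated (average-precision) estimator, which avoids the
    optimistic bias of trapezoidal interpolation on imbalanced data.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise InputError("ROC/PR curves need both classes present")
    if np.ptp(s) == 0:
        warnings.warn("constant scores: ROC AUC reported as 0.5")
    fpr, tpr, roc_thr = skm.roc_curve(y, s)
    precision, recall, pr_thr = skm.precision_recall_curve(y, s)
    roc_auc = 0.5 if np.ptp(s) == 0 else float(skm.auc(fpr, tpr))
    return {
        "roc": pd.DataFrame({"fpr": fpr, "tpr": tpr,
                             "threshold": np.r_[np.inf, roc_thr[1:]] if len(roc_thr) else roc_thr}),
        "pr": pd.DataFrame({"recall": recall, "precision": precision}),
        "roc_auc": roc_auc,
        "pr_auc": float(skm.average_precision_score(y, s)),
    }


# ---------------------------------------------------------------------------
# permutation test & benchmarking

@dataclass
class PermutationResult:
    observed: MetricsReport
    permuted: pd.DataFrame          # one row per permutation, metric columns
    p_values: dict[str, float]
    n_permutations: int
    seed: Optional[int]
    set_sizes: tuple[int, int] = (2, 4)


def _fit_and_score(features: pd.DataFrame, labels, svm_params: Mapping) -> tuple[MetricsReport, Gd2Svm]:
    model = Gd2Svm(**dict(svm_params)).fit(features, labels)
    scores = model.decision_function(features)
    rep = classification_metrics(labels, (scores > 0).astype(int), scores)
    rep.support_vector_count = model.n_support_
    return rep, model


def permutation_test(
    ras_matrix: pd.DataFrame,
    reaction_ids: Sequence[str],
    labels,
    observed_set: ReactionSet,
    n_permutations: int = 10_000,
    seed: Optional[int] = None,
    svm_params: Optional[Mapping] = None,
    p_convention: str = "strict",
) -> PermutationResult:
    """Empirical test of whether the curated reaction set beats random ones.

    Each iteration draws 2 promoting + 4 mitigating reaction labels
    uniformly without replacement from ``reaction_ids`` (the draw of 6 is
    disjoint within an iteration; overlap with the curated set across
    iterations is allowed), trains the configured SVM on the summed
    features, and records training-set metrics.  The empirical p-value per
    metric is the fraction of permutations with a *strictly greater* value
    than the observed one (``p_convention="plus_one"`` switches to the
    (count+1)/(N+1) estimate).  Iterations whose model degenerates to a
    single predicted class record 0 for the undefined metrics and still
    count toward N.
    """
    if n_permutations < 1:
        raise InputError("n_permutations must be >= 1")
    reaction_ids = list(reaction_ids)
    n_prom = len(observed_set.promoting) or 2
    n_mit = len(observed_set.mitigating) or 4
    if len(reaction_ids) < n_prom + n_mit:
        raise InputError(
            f"graph has {len(reaction_ids)} reactions; need at least {n_prom + n_mit}"
        )
    svm_params = svm_params or {"kernel": "linear", "C": 1.0, "scaling": "scaled"}
    labels = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)

    observed, _ = _fit_and_score(
        aggregate_features(ras_matrix, observed_set), labels, svm_params
    )

    rows = np.empty((n_permutations, len(PERMUTATION_METRICS)))
    for i in range(n_permutations):
        draw = rng.choice(reaction_ids, size=n_prom + n_mit, replace=False)
        rand_set = ReactionSet("perm", list(draw[:n_prom]), list(draw[n_prom:]))
        feats = aggregate_features(ras_matrix, rand_set)
        try:
            rep, _ = _fit_and_score(feats, labels, svm_params)
            rows[i] = [getattr(rep, m) for m in PERMUTATION_METRICS]
        except InputError:
            rows[i] = 0.0
    permuted = pd.DataFrame(rows, columns=list(PERMUTATION_METRICS))

    p_values = {}
    for m in PERMUTATION_METRICS:
        count = int((permuted[m].to_numpy() > getattr(observed, m)).sum())
        if p_convention == "plus_one":
            p_values[m] = (count + 1) / (n_permutations + 1)
        else:
            p_values[m] = count / n_permutations
    return PermutationResult(observed, permuted, p_values, n_permutations, seed,
                             (n_prom, n_mit))


def benchmark_reaction_sets(
    reaction_sets: Sequence[ReactionSet],
    ras_variants: Mapping[str, pd.DataFrame],
    labels,
    svm_params: Optional[Mapping] = None,
) -> pd.DataFrame:
    """Metrics for every reaction set x RAS variant combination.

    ``ras_variants`` maps a variant tag (``ras`` / ``rasTP`` / ``rasTPrec``)
    to a samples x reactions matrix.  Returns one row per (set, variant)
    with the full metric report, SV count included.
    """
    svm_params = svm_params or {"kernel": "linear", "C": 1.0, "scaling": "scaled"}
    labels = np.asarray(labels).astype(int)
    records = []
    for rset in reaction_sets:
        for variant, ras in ras_variants.items():
            feats = aggregate_features(ras, rset)
            rep, _ = _fit_and_score(feats, labels, svm_params)
            rec = {"reaction_set": rset.name, "variant": variant}
            rec.update(rep.to_dict())
            records.append(rec)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# nonparametric group statistics

def wilcoxon_rank_sum(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both groups have n <= 10 and there are no ties;
    otherwise the tie-corrected normal approximation without continuity
    correction (matching the rank-based post hoc conventions used
    alongside it).  Returns ``(U statistic of group A, p)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InputError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(a) <= 10 and len(b) <= 10 and no_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def cliffs_delta(group_a, group_b) -> float:
    """Cliff's delta effect size: (#{a>b} - #{a<b}) / (nA * nB)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InputError("both groups must be nonempty")
    diff = a[:, None] - b[None, :]
    return float(((diff > 0).sum() - (diff < 0).sum()) / diff.size)


def kruskal_wallis(groups: Sequence) -> dict:
    """Tie-corrected Kruskal-Wallis test with eta-squared effect size.

    eta^2 = (H - k + 1) / (n - k), floored at 0 (slightly negative values
    arise for tiny H and are not interpretable as an effect size).  All
    values identical across groups gives H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InputError("need at least two groups")
    k = len(groups)
    n = sum(len(g) for g in groups)
    if n <= k:
        raise InputError("total sample size must exceed the number of groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return {"H": 0.0, "p": 1.0, "eta_squared": 0.0, "df": k - 1, "n": n}
    H, p = sps.kruskal(*groups)
    eta2 = max(0.0, (H - k + 1) / (n - k))
    return {"H": float(H), "p": float(p), "eta_squared": float(eta2),
            "df": k - 1, "n": n}


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def dunn_posthoc(groups: Mapping[str, Sequence] | Sequence,
                 p_adjust: str = "bh") -> pd.DataFrame:
    """Dunn's post hoc test with tie correction after Kruskal-Wallis.

    Pairwise z statistics use the pooled-rank variance
    ``(N(N+1)/12 - T/(12(N-1))) * (1/ni + 1/nj)`` with the usual tie term
    ``T = sum(t^3 - t)``.  p-values are two-sided normal and BH-adjusted by
    default (``p_adjust=None`` disables adjustment).  Empty groups are
    excluded with a warning.
    """
    if isinstance(groups, Mapping):
        named = [(str(k), np.asarray(v, dtype=float)) for k, v in groups.items()]
    else:
        named = [(str(i), np.asarray(g, dtype=float)) for i, g in enumerate(groups)]
    kept = []
    for name, g in named:
        if len(g) == 0:
            warnings.warn(f"group {name!r} is empty; excluded from Dunn's test")
        else:
            kept.append((name, g))
    if len(kept) < 2:
        raise InputError("Dunn's test needs at least two nonempty groups")
    pooled = np.concatenate([g for _, g in kept])
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    pos = 0
    for name, g in kept:
        mean_ranks[name] = ranks[pos:pos + len(g)].mean()
        sizes[name] = len(g)
        pos += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3) - counts).sum())
    var_base = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    rows = []
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            ni, nj = kept[i][0], kept[j][0]
            se = np.sqrt(var_base * (1.0 / sizes[ni] + 1.0 / sizes[nj]))
            z = (mean_ranks[ni] - mean_ranks[nj]) / se if se > 0 else 0.0
            p = 2 * sps.norm.sf(abs(z))
            rows.append({"group1": ni, "group2": nj, "z": z, "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"]) if p_adjust == "bh" else table["p"]
    return table
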