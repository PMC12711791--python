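"""Metrics, curves, permutation machinery, and nonparametric statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import gd2flux as g
from gd2flux.errors import InputError


# -- classification metrics -------------------------------------------------

def test_balanced_accuracy_identity():
    """Sensitivity 0.60 with specificity 1.00 gives balanced accuracy 0.80."""
    y = np.r_[np.ones(10, dtype=int), np.zeros(20, dtype=int)]
    yhat = np.r_[np.ones(6), np.zeros(4), np.zeros(20)].astype(int)
    rep = g.classification_metrics(y, yhat)
    assert rep.recall == pytest.approx(0.60)
    assert rep.specificity == 1.0
    assert rep.balanced_accuracy == pytest.approx(0.80)
    assert rep.balanced_accuracy == (rep.recall + rep.specificity) / 2


def test_perfect_predictions():
    y = np.array([1, 0, 1, 0])
    rep = g.classification_metrics(y, y, scores=np.array([2.0, -1.0, 3.0, -2.0]))
    for name in ("balanced_accuracy", "precision", "recall", "f1", "accuracy",
                 "specificity", "roc_auc", "pr_auc"):
        assert getattr(rep, name) == 1.0


def test_hand_computed_confusion_matrix():
    """TP=3, FN=1, FP=0, TN=6 -> precision 1, recall 3/4, F1 6/7."""
    y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
    yhat = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
    rep = g.classification_metrics(y, yhat)
    assert rep.precision == 1.0
    assert rep.recall == pytest.approx(0.75)
    assert rep.f1 == pytest.approx(6 / 7)
    assert rep.detection_rate == pytest.approx(0.3)
    assert rep.detection_prevalence == pytest.approx(0.3)


def test_single_class_labels_leave_aucs_absent():
    rep = g.classification_metrics([1, 1], [1, 0], scores=[0.2, 0.4])
    assert rep.roc_auc is None and rep.pr_auc is None


# -- ROC / PR ----------------------------------------------------------------

def _concordance_auc(y, s):
    """Mann-Whitney concordance probability (independent of the sweep)."""
    pos = [v for v, t in zip(s, y) if t == 1]
    neg = [v for v, t in zip(s, y) if t == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def test_roc_auc_examples():
    assert g.roc_pr_curves([0, 1, 0, 1], [0.1, 0.9, 0.2, 0.8])["roc_auc"] == 1.0
    assert g.roc_pr_curves([0, 0, 1, 1], [0.9, 0.8, 0.2, 0.1])["roc_auc"] == 0.0
    out = g.roc_pr_curves([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8])
    assert out["roc_auc"] == pytest.approx(0.75)


def test_constant_scores_report_half_with_warning():
    with pytest.warns(UserWarning, match="constant scores"):
        out = g.roc_pr_curves([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
    assert out["roc_auc"] == 0.5


def test_roc_auc_equals_concordance_probability():
    rng = np.random.default_rng(0)
    for _ in range(50):
        y = rng.integers(0, 2, size=30)
        if y.min() == y.max():
            continue
        s = np.round(rng.normal(size=30), 1)  # rounded -> ties exercised
        out = g.roc_pr_curves(y, s)
        assert out["roc_auc"] == pytest.approx(_concordance_auc(y, s), abs=1e-9)


# -- Wilcoxon / Cliff's delta ------------------------------------------------

def test_wilcoxon_exact_enumeration_extreme_ordering():
    _, p = g.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
    assert p == pytest.approx(0.1)  # 2/C(6,3) = 2/20


def test_wilcoxon_exhaustive_oracle_small_groups():
    """Exact p equals enumeration over all rank assignments."""
    a, b = [1.0, 4.0, 7.0, 9.5], [2.0, 3.0, 8.0]
    u_obs, p = g.wilcoxon_rank_sum(a, b)
    pooled = sorted(a + b)
    n_a = len(a)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = sum(1 for x in xs for y in ys if x > y)
        total += 1
        u_mid = n_a * len(ys) / 2
        if abs(u - u_mid) >= abs(u_obs - u_mid):
            count += 1
    assert p == pytest.approx(count / total)


def test_wilcoxon_identical_groups_and_shift_monotonicity():
    assert g.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])[1] == pytest.approx(1.0)
    _, p_near = g.wilcoxon_rank_sum([1, 2, 3], [2, 3, 4])
    _, p_far = g.wilcoxon_rank_sum([1, 2, 3], [100, 101, 102])
    assert p_far <= p_near
    with pytest.raises(InputError):
        g.wilcoxon_rank_sum([], [1.0])


def test_cliffs_delta_brute_force_cases():
    assert g.cliffs_delta([1, 2, 3], [4, 5, 6]) == -1.0
    assert g.cliffs_delta([1, 2, 3], [1, 2, 3]) == 0.0
    assert g.cliffs_delta([1, 3], [2]) == 0.0  # one pair greater, one lesser
    rng = np.random.default_rng(4)
    a, b = rng.normal(size=9), rng.normal(size=7)
    brute = np.mean([np.sign(x - y) for x in a for y in b])
    assert g.cliffs_delta(a, b) == pytest.approx(brute)


# -- Kruskal-Wallis / Dunn / BH ----------------------------------------------

def test_eta_squared_formula():
    # direct formula check at H=10, k=3, n=50 (flooring irrelevant here)
    assert (10 - 3 + 1) / (50 - 3) == pytest.approx(8 / 47)
    rng = np.random.default_rng(1)
    groups = [rng.normal(loc, 1, 20) for loc in (0, 1, 2)]
    kw = g.kruskal_wallis(groups)
    assert kw["eta_squared"] == pytest.approx((kw["H"] - 3 + 1) / (kw["n"] - 3))


def test_two_group_kruskal_matches_squared_wilcoxon_z():
    rng = np.random.default_rng(2)
    a, b = rng.normal(0, 1, 15), rng.normal(0.8, 1, 12)
    kw = g.kruskal_wallis([a, b])
    _, p = g.wilcoxon_rank_sum(a, b)
    z = sps.norm.isf(p / 2)
    assert kw["H"] == pytest.approx(z ** 2, rel=1e-9)


def test_identical_groups_give_zero_h_unit_p():
    kw = g.kruskal_wallis([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
    assert kw["H"] == 0.0 and kw["p"] == 1.0 and kw["eta_squared"] == 0.0


def test_dunn_two_groups_equals_wilcoxon_normal_approximation():
    rng = np.random.default_rng(3)
    a, b = rng.normal(0, 1, 14), rng.normal(0.5, 1, 11)
    table = g.dunn_posthoc({"a": a, "b": b}, p_adjust=None)
    _, p_wilcox = g.wilcoxon_rank_sum(a, b)
    assert table["p"].iloc[0] == pytest.approx(p_wilcox, rel=1e-9)


def test_dunn_identical_groups_all_unit_p():
    groups = {"a": [1.0] * 6, "b": [1.0] * 6, "c": [1.0] * 6}
    table = g.dunn_posthoc(groups)
    assert (table["p_adj"] == 1.0).all()


def test_bh_step_up_hand_checked_and_monotone():
    np.testing.assert_allclose(g.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    rng = np.random.default_rng(5)
    p = rng.uniform(size=40)
    adj = g.bh_adjust(p)
    assert (adj >= p - 1e-15).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-15).all()


# -- permutation test & benchmarking -----------------------------------------

def test_permutation_p_value_conventions(cohort, ganglio):
    _, _, r1 = ganglio
    res = g.permutation_test(cohort["rasTP"], list(cohort["rasTP"].columns),
                             cohort["labels"], r1, n_permutations=25, seed=0)
    for metric, p in res.p_values.items():
        count = int((res.permuted[metric] > getattr(res.observed, metric)).sum())
        assert p == count / 25
    res2 = g.permutation_test(cohort["rasTP"], list(cohort["rasTP"].columns),
                              cohort["labels"], r1, n_permutations=25, seed=0,
                              p_convention="plus_one")
    for metric, p in res2.p_values.items():
        assert 0 < p <= 1


def test_permutation_needs_enough_reactions(cohort, ganglio):
    _, _, r1 = ganglio
    small = cohort["rasTP"][["R05946", "R05940"]]
    with pytest.raises(InputError, match="at least"):
        g.permutation_test(small, list(small.columns), cohort["labels"], r1,
                           n_permutations=5, seed=0)


def test_benchmark_duplicate_set_gives_identical_metrics(cohort, ganglio):
    _, _, r1 = ganglio
    twin = g.ReactionSet("r1_twin", list(r1.promoting), list(r1.mitigating))
    table = g.benchmark_reaction_sets(
        [r1, twin], {"ras": cohort["ras"], "rasTP": cohort["rasTP"]},
        cohort["labels"])
    assert len(table) == 4
    for variant in ("ras", "rasTP"):
        rows = table[table["variant"] == variant].set_index("reaction_set")
        assert rows.loc["r1", "balanced_accuracy"] == rows.loc["r1_twin", "balanced_accuracy"]
        assert rows.loc["r1", "pr_auc"] == rows.loc["r1_twin", "pr_auc"]


def test_benchmark_uninformative_upstream_set_underperforms(cohort, ganglio):
    """The curated set outranks a far-upstream set on balanced accuracy."""
    _, _, r1 = ganglio
    upstream = g.ReactionSet("stem", ["R01496", "R01281"], ["R05937"])
    table = g.benchmark_reaction_sets(
        [r1, upstream], {"rasTP": cohort["rasTP"]}, cohort["labels"])
    rows = table.set_index("reaction_set")
    assert rows.loc["r1", "balanced_accuracy"] > rows.loc["stem", "balanced_accuracy"]
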