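"""Frozen median-of-ratios normalization against an independent oracle."""

import numpy as np
import pandas as pd
import pytest

import gd2flux as g
from gd2flux.errors import InputError


# -- independent reference implementation (plain loops, no pandas) ----------

def reference_size_factors(counts_genes_by_samples: np.ndarray) -> np.ndarray:
    """Standard within-dataset median-of-ratios size factors."""
    x = np.asarray(counts_genes_by_samples, dtype=float)
    usable = [i for i in range(x.shape[0]) if all(x[i, j] > 0 for j in range(x.shape[1]))]
    geomeans = {i: float(np.exp(np.mean(np.log(x[i])))) for i in usable}
    factors = []
    for j in range(x.shape[1]):
        ratios = sorted(x[i, j] / geomeans[i] for i in usable)
        mid = len(ratios) // 2
        med = ratios[mid] if len(ratios) % 2 else (ratios[mid - 1] + ratios[mid]) / 2
        factors.append(med)
    return np.array(factors)


def _frame(genes_by_samples, genes=None, samples=None) -> pd.DataFrame:
    arr = np.asarray(genes_by_samples, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=samples).T  # samples x genes


def test_textbook_two_by_two_fit():
    """geomeans (8, 2); ratio medians 0.5 and 2 — arithmetic forced by the
    median-of-ratios definition."""
    norm = g.FrozenMedianOfRatios().fit(_frame([[4, 16], [1, 4]]))
    assert norm.reference_geomeans_.to_list() == pytest.approx([8.0, 2.0])
    assert norm.training_ratio_medians_.to_list() == pytest.approx([0.5, 2.0])


def test_identical_columns_yield_equal_medians():
    norm = g.FrozenMedianOfRatios().fit(_frame([[5, 5, 5], [2, 2, 2], [9, 9, 9]]))
    assert norm.training_ratio_medians_.nunique() == 1


def test_gene_with_zero_count_excluded_from_reference():
    counts = np.array([[4.0, 16.0], [1.0, 4.0], [0.0, 7.0]])
    norm = g.FrozenMedianOfRatios().fit(_frame(counts))
    assert "g2" not in norm.usable_genes_
    expected = reference_size_factors(counts)
    np.testing.assert_allclose(norm.training_ratio_medians_.to_numpy(), expected, atol=1e-12)


def test_new_sample_size_factor_hand_computed():
    """m* = median(8/8, 2/2) = 1; s* = 1 / mean(0.5, 2) = 0.8."""
    norm = g.FrozenMedianOfRatios().fit(_frame([[4, 16], [1, 4]]))
    new = _frame([[8], [2]], samples=["new"])
    assert norm.size_factors(new).to_list() == pytest.approx([0.8])


def test_sum_denominator_convention():
    norm = g.FrozenMedianOfRatios(denominator="sum").fit(_frame([[4, 16], [1, 4]]))
    new = _frame([[8], [2]], samples=["new"])
    assert norm.size_factors(new).to_list() == pytest.approx([1.0 / 2.5])


def test_training_factors_proportional_to_standard_estimator():
    """Frozen factors on the training data equal the classic size factors
    divided by the global constant, against the loop-based oracle."""
    rng = np.random.default_rng(5)
    counts = rng.poisson(60, size=(40, 8)).astype(float)
    counts[3, 2] = 0.0  # one unusable gene
    X = _frame(counts)
    norm = g.FrozenMedianOfRatios().fit(X)
    standard = reference_size_factors(counts)
    frozen = norm.size_factors(X).to_numpy()
    np.testing.assert_allclose(frozen, standard / standard.mean(), atol=1e-10)


def test_homogeneity_in_sample_counts():
    rng = np.random.default_rng(6)
    counts = rng.poisson(40, size=(30, 5)).astype(float) + 1
    norm = g.FrozenMedianOfRatios().fit(_frame(counts))
    new = _frame(counts[:, :1] * 3.7, samples=["scaled"])
    base = _frame(counts[:, :1], samples=["plain"])
    assert norm.size_factors(new).iloc[0] == pytest.approx(
        3.7 * norm.size_factors(base).iloc[0], rel=1e-12)


def test_gene_order_permutation_invariance():
    rng = np.random.default_rng(7)
    counts = rng.poisson(30, size=(20, 4)).astype(float) + 1
    X = _frame(counts)
    perm = X.iloc[:, rng.permutation(X.shape[1])]
    f1 = g.FrozenMedianOfRatios().fit(X).size_factors(X)
    f2 = g.FrozenMedianOfRatios().fit(perm).size_factors(perm)
    np.testing.assert_allclose(f1.to_numpy(), f2.to_numpy(), atol=1e-12)


def test_degenerate_inputs_raise():
    with pytest.raises(InputError):  # single sample
        g.FrozenMedianOfRatios().fit(_frame([[3], [1]]))
    with pytest.raises(InputError):  # no all-positive gene
        g.FrozenMedianOfRatios().fit(_frame([[0, 3], [2, 0]]))
    norm = g.FrozenMedianOfRatios().fit(_frame([[4, 16], [1, 4]]))
    with pytest.raises(InputError, match="all-zero"):
        norm.size_factors(_frame([[0], [0]], samples=["dead"]))
    disjoint = pd.DataFrame([[1.0, 2.0]], index=["x"], columns=["h1", "h2"])
    with pytest.raises(InputError, match="overlap"):
        norm.size_factors(disjoint)


def test_log_transform_values_and_monotonicity():
    assert g.log_transform(np.array([99.0]))[0] == pytest.approx(2.0)
    assert g.log_transform(np.array([0.0]))[0] == 0.0
    x = np.sort(np.random.default_rng(0).uniform(0, 50, 20))
    assert (np.diff(g.log_transform(x)) > 0).all()
    with pytest.raises(InputError):
        g.log_transform(np.array([-2.0]), pseudocount=1.0)


def test_normalizer_json_round_trip(tmp_path, cohort):
    norm = cohort["normalizer"]
    path = tmp_path / "ref.json"
    norm.to_json(path)
    back = g.FrozenMedianOfRatios.from_json(path)
    X = cohort["counts"].T
    np.testing.assert_array_equal(norm.size_factors(X).to_numpy(),
                                  back.size_factors(X).to_numpy())
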