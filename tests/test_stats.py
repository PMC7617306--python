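import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clonefate.errors import UndefinedDiversityError
from clonefate.stats import (bh_adjust, diff_abundance, diversity_table,
                             shannon_diversity, variability)

# ---------------------------------------------------------------- Shannon


def test_shannon_uniform_is_log_k():
    assert shannon_diversity([5, 5, 5, 5]) == pytest.approx(np.log(4))


def test_shannon_single_clone_is_zero():
    assert shannon_diversity([42]) == pytest.approx(0.0)


def test_shannon_direct_evaluation():
    # -(0.25 ln 0.25 * 2 + 0.5 ln 0.5)
    assert shannon_diversity([1, 1, 2]) == pytest.approx(1.0397, abs=1e-4)


def test_shannon_all_zero_is_undefined():
    with pytest.raises(UndefinedDiversityError):
        shannon_diversity([0, 0, 0])


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.integers(min_value=0, max_value=1000), min_size=1,
                max_size=20).filter(lambda x: sum(x) > 0),
       st.integers(min_value=1, max_value=7))
def test_shannon_invariances(counts, scale):
    """Permutation invariant; unchanged by scaling all counts; maximal at
    uniform frequencies."""
    h = shannon_diversity(counts)
    assert h == pytest.approx(shannon_diversity(sorted(counts)))
    assert h == pytest.approx(shannon_diversity([scale * c for c in counts]))
    k = sum(1 for c in counts if c > 0)
    assert h <= np.log(k) + 1e-9


def test_diversity_table_counts_detected():
    table = diversity_table(pd.DataFrame({"s1": [4, 4, 0], "s2": [1, 1, 2]}))
    assert table.loc["s1", "n_detected"] == 2
    assert table.loc["s1", "shannon"] == pytest.approx(np.log(2))


# ------------------------------------------------------------- variability


@pytest.mark.parametrize("x,expected", [
    ((3, 3, 3), 0.0),          # constant vector
    ((7, 3, 1), 2.0),          # log2(8/2)
    ((0, 0, 0), 0.0),          # zero vector
    ((15, 3, 0), 4.0),         # log2(16/1)
])
def test_variability_fixtures(x, expected):
    assert variability(x) == pytest.approx(expected)


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1e6), min_size=1, max_size=9))
def test_variability_nonnegative_and_permutation_invariant(x):
    v = variability(x)
    assert v >= 0
    assert v == pytest.approx(variability(sorted(x, reverse=True)))


def test_variability_weakly_increasing_in_spread():
    assert variability([8, 4, 2]) <= variability([16, 4, 2])
    assert variability([8, 4, 2]) <= variability([8, 4, 1])


# --------------------------------------------------------------------- BH


def _bh_brute(p):
    """Literal step-up: sort, q_i = p_i * m / rank, enforce monotonicity
    from the largest rank down, cap at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def test_bh_worked_example():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                               [0.03, 0.03, 0.03])


def test_bh_single_and_capped():
    np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
    np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


def test_bh_equals_brute_force_on_permutations():
    base = [0.003, 0.04, 0.04, 0.2, 0.77, 1.0]
    for perm in itertools.permutations(base):
        np.testing.assert_allclose(bh_adjust(list(perm)), _bh_brute(perm),
                                   atol=1e-12)


@settings(max_examples=80, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=6))
def test_bh_equals_brute_force_random(p):
    np.testing.assert_allclose(bh_adjust(p), _bh_brute(p), atol=1e-12)


# ------------------------------------------------------- NB Wald test


def _frame(x, prefix):
    return pd.DataFrame(x, columns=[f"{prefix}{i}" for i in range(x.shape[1])])


def test_identical_arms_give_null_result():
    counts = pd.DataFrame({"n0": [5, 9], "n1": [5, 9], "n2": [5, 9],
                           "a0": [5, 9], "a1": [5, 9], "a2": [5, 9]})
    sf = pd.Series(1.0, index=counts.columns)
    res = diff_abundance(counts, ["n0", "n1", "n2"], ["a0", "a1", "a2"], sf)
    np.testing.assert_allclose(res["log2fc"], 0.0)
    np.testing.assert_allclose(res["p"], 1.0)


def test_all_zero_barcode_is_flagged_null():
    counts = pd.DataFrame(
        {c: [0, 10] for c in ["n0", "n1", "n2", "a0", "a1", "a2"]})
    sf = pd.Series(1.0, index=counts.columns)
    res = diff_abundance(counts, ["n0", "n1", "n2"], ["a0", "a1", "a2"], sf)
    assert bool(res["all_zero"].iloc[0])
    assert res.loc[0, "log2fc"] == 0.0
    assert res.loc[0, "p"] == 1.0


def test_poisson_eightfold_difference_recovers_lfc():
    """Large-count consistency: Poisson draws around an exact 8-fold
    difference estimate the log2 fold change within 0.1 of 3."""
    rng = np.random.default_rng(9)
    n_bc = 200
    nk = rng.poisson(4000.0, size=(n_bc, 3))
    alone = rng.poisson(500.0, size=(n_bc, 3))
    counts = pd.concat([_frame(nk, "n"), _frame(alone, "a")], axis=1)
    sf = pd.Series(1.0, index=counts.columns)
    res = diff_abundance(counts, ["n0", "n1", "n2"], ["a0", "a1", "a2"], sf)
    assert np.abs(res["log2fc"].mean() - 3.0) < 0.1
    assert (np.abs(res["log2fc"] - 3.0) < 0.35).all()


def test_dispersion_moderation_reduces_to_poisson_limit():
    """As dispersion -> 0 the test agrees with an exact two-sample Poisson
    comparison (conditional binomial oracle) on which barcodes differ."""
    from scipy.stats import binomtest
    rng = np.random.default_rng(12)
    n_bc = 60
    mu_a = 800.0
    shift = np.where(np.arange(n_bc) < 30, 8.0, 1.0)  # half with 8-fold change
    nk = rng.poisson(mu_a * shift[:, None], size=(n_bc, 3))
    alone = rng.poisson(mu_a, size=(n_bc, 3))
    counts = pd.concat([_frame(nk, "n"), _frame(alone, "a")], axis=1)
    sf = pd.Series(1.0, index=counts.columns)
    res = diff_abundance(counts, ["n0", "n1", "n2"], ["a0", "a1", "a2"], sf)
    oracle = np.array([
        binomtest(int(nk[i].sum()), int(nk[i].sum() + alone[i].sum()),
                  0.5).pvalue
        for i in range(n_bc)])
    assert ((res["p"] < 0.01) == (oracle < 1e-6))[:30].all()
    # nulls: neither route should reject wholesale
    assert (res["p"] > 0.01)[30:].mean() > 0.8
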