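"""Association statistics against closed forms and independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohortnet.associations import (
    InsufficientDataError,
    UndefinedCorrelationError,
    default_n_bins,
    mutual_information_binned,
    normalized_mi,
    pair_association,
    pearson,
    permutation_pvalue,
)


def mi_oracle(counts: np.ndarray) -> float:
    """Direct plug-in summation over the contingency table, in nats."""
    n = counts.sum()
    mi = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            nij = counts[i, j]
            if nij > 0:
                mi += (nij / n) * math.log(
                    (nij / n) / ((counts[i].sum() / n) * (counts[:, j].sum() / n))
                )
    return mi


def expand(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Samples realizing a given discrete contingency table."""
    xs, ys = [], []
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            xs += [i] * int(counts[i, j])
            ys += [j] * int(counts[i, j])
    return np.array(xs, float), np.array(ys, float)


def test_perfect_binary_dependence_is_log2():
    x, y = expand(np.array([[50, 0], [0, 50]]))
    assert mutual_information_binned(x, y, discrete=(True, True)) == pytest.approx(
        math.log(2), rel=1e-12
    )


def test_identical_discrete_variable_recovers_own_entropy():
    x = np.repeat([0.0, 1.0, 2.0, 3.0], 100)
    mi = mutual_information_binned(x, x, discrete=(True, True))
    assert mi == pytest.approx(math.log(4), rel=1e-12)
    assert normalized_mi(x, x, discrete=(True, True)) == pytest.approx(1.0)


def test_independent_uniforms_have_near_zero_mi():
    rng = np.random.default_rng(0)
    n = 100_000
    x, y = rng.random(n), rng.random(n)
    mi = mutual_information_binned(x, y, n_bins=10)
    # plug-in bias ~ (bins-1)^2 / (2N) = 4.05e-4; allow generous slack
    assert 0.0 <= mi < 0.01


def test_nmi_on_printed_2x2_table_matches_direct_summation():
    counts = np.array([[40, 10], [10, 40]])
    x, y = expand(counts)
    mi = mi_oracle(counts)
    h = -sum(p * math.log(p) for p in (0.5, 0.5))  # both marginals are (50, 50)
    assert normalized_mi(x, y, discrete=(True, True)) == pytest.approx(
        mi / h, rel=1e-12
    )


def test_mi_matches_oracle_on_random_small_tables():
    rng = np.random.default_rng(123)
    for _ in range(50):
        kx, ky = rng.integers(2, 6, size=2)
        counts = rng.integers(0, 30, size=(kx, ky))
        if counts.sum() < 2 or counts.any(axis=1).sum() < 1:
            continue
        x, y = expand(counts)
        got = mutual_information_binned(x, y, discrete=(True, True))
        assert got == pytest.approx(max(0.0, mi_oracle(counts)), rel=1e-12, abs=1e-12)


def test_mi_matches_sklearn_reference():
    sk = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(7)
    for _ in range(20):
        x = rng.integers(0, 4, size=300).astype(float)
        y = np.where(rng.random(300) < 0.5, x, rng.integers(0, 4, size=300)).astype(float)
        ours = mutual_information_binned(x, y, discrete=(True, True))
        ref = sk.mutual_info_score(x, y)
        assert ours == pytest.approx(ref, rel=1e-10, abs=1e-12)


def test_constant_vector_gives_zero_mi_not_error():
    x = np.zeros(50)
    y = np.arange(50.0)
    assert mutual_information_binned(x, y) == 0.0
    assert normalized_mi(x, y) == 0.0


def test_insufficient_data_raises():
    with pytest.raises(InsufficientDataError):
        mutual_information_binned([1.0, np.nan], [np.nan, 2.0])
    with pytest.raises(InsufficientDataError):
        pearson([1.0], [2.0])


def test_pearson_closed_forms():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
    assert pearson(x, -x) == pytest.approx(-1.0)
    assert pearson(x, np.array([1.0, 3.0, 2.0, 4.0])) == pytest.approx(0.8)
    with pytest.raises(UndefinedCorrelationError):
        pearson(x, np.ones(4))


def test_default_bin_count_rule():
    assert default_n_bins(500) == 10
    assert default_n_bins(125) == 5
    assert default_n_bins(5) == 2  # floor at 2


@given(st.integers(0, 2**31 - 2))
@settings(max_examples=15, deadline=None)
def test_statistics_symmetric_in_the_pair(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=60)
    y = x * 0.5 + rng.normal(size=60)
    x[rng.integers(0, 60, 5)] = np.nan
    assert mutual_information_binned(x, y) == pytest.approx(
        mutual_information_binned(y, x), rel=1e-12
    )
    assert normalized_mi(x, y) == pytest.approx(normalized_mi(y, x), rel=1e-12)
    assert pearson(x, y) == pytest.approx(pearson(y, x), rel=1e-12)


@given(st.integers(0, 2**31 - 2), st.integers(1, 30))
@settings(max_examples=15, deadline=None)
def test_jointly_missing_rows_never_change_statistics(seed, n_extra):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=80)
    y = 0.7 * x + rng.normal(size=80)
    xp = np.concatenate([x, np.full(n_extra, np.nan)])
    yp = np.concatenate([y, np.full(n_extra, np.nan)])
    assert mutual_information_binned(xp, yp) == mutual_information_binned(x, y)
    assert pearson(xp, yp) == pearson(x, y)
    assert permutation_pvalue("mi", xp, yp, n_perm=50, seed=1) == permutation_pvalue(
        "mi", x, y, n_perm=50, seed=1
    )


def test_pvalue_lower_bound_is_add_one():
    rng = np.random.default_rng(0)
    x = rng.normal(size=200)
    p = permutation_pvalue("mi", x, x.copy(), n_perm=1000, seed=0)
    assert p == pytest.approx(1 / 1001)


def test_exact_copy_is_significant():
    rng = np.random.default_rng(1)
    x = rng.normal(size=200)
    assert permutation_pvalue("mi", x, x.copy(), n_perm=200, seed=3) < 0.05
    assert permutation_pvalue("pearson", x, x.copy(), n_perm=200, seed=3) < 0.05


def test_callable_statistic_matches_builtin_pearson_pvalue():
    rng = np.random.default_rng(4)
    x = rng.normal(size=60)
    y = 0.4 * x + rng.normal(size=60)

    def absr(a, b):
        return abs(np.corrcoef(a, b)[0, 1])

    p_custom = permutation_pvalue(absr, x, y, n_perm=400, tails="one", seed=9)
    p_fast = permutation_pvalue("pearson", x, y, n_perm=400, tails="two", seed=9)
    # same test up to Monte Carlo error of two independent permutation streams
    assert abs(p_custom - p_fast) < 0.07


def test_pair_association_bundles_consistent_fields(small_cohort):
    _, t = small_cohort
    res = pair_association(t.data["alpha_000"], t.data["alpha_001"],
                           var_a="alpha_000", var_b="alpha_001",
                           n_perm=200, seed=0)
    assert res.n_complete == 400
    assert res.mi >= 0 and 0 <= res.nmi <= 1 and -1 <= res.r <= 1
    assert res.p_mi < 0.05 and res.p_r < 0.05  # block pair, loading 0.8
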