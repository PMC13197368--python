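"""Reliability coefficients, correlation, and mediation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_session
from dualprobe import psychometrics as psy
from dualprobe.psychometrics import (
    EstimationError,
    build_item_matrix,
    cronbach_alpha,
    kr20,
    mediate,
    pearson_with_test,
    r_to_d,
    spearman_brown,
    split_half_oddeven,
    split_half_permutation,
)
from dualprobe.scoring import score_session


# --- KR-20 / alpha --------------------------------------------------------


def test_kr20_two_by_two_hand_computation():
    """Rows (1,1) and (0,0): p = (.5,.5), sum pq = .5, population var = 1 -> 1.0."""
    m = np.array([[1.0, 1.0], [0.0, 0.0]])
    assert kr20(m) == pytest.approx(1.0)
    assert cronbach_alpha(m) == pytest.approx(1.0)


def test_kr20_independent_items_near_zero(rng):
    m = (rng.random((2000, 40)) < 0.5).astype(float)
    assert abs(kr20(m)) < 0.1


def test_kr20_equals_alpha_on_complete_binary(rng):
    """On complete dichotomous data KR-20 is algebraically Cronbach's alpha."""
    for _ in range(50):
        n = rng.integers(5, 40)
        k = rng.integers(2, 30)
        m = (rng.random((n, k)) < rng.uniform(0.2, 0.8)).astype(float)
        try:
            a = kr20(m)
        except EstimationError:
            continue
        assert a == pytest.approx(cronbach_alpha(m), abs=1e-12)


def test_alpha_against_pingouin_oracle(rng):
    """Independent implementation check on a continuous matrix.

    pingouin uses the sample-variance convention, so compare after
    rescaling by the (n-1)/n factors, which cancel in the variance ratio.
    """
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    m = rng.normal(size=(60, 8)) + rng.normal(size=(60, 1))
    ours = cronbach_alpha(m)
    theirs = float(pingouin.cronbach_alpha(data=pd.DataFrame(m))[0])
    assert ours == pytest.approx(theirs, abs=1e-10)


def test_kr20_degenerate_inputs():
    with pytest.raises(EstimationError):
        kr20(np.ones((5, 5)))  # zero total-score variance
    with pytest.raises(EstimationError):
        kr20(np.array([[1.0, 0.0]]))  # single person


def test_kr20_mean_imputation_consistency():
    """Missing entries imputed to p_j leave a complete matrix unchanged."""
    m = np.array([[1, 0, 1], [0, 1, 1], [1, 1, 0], [0, 0, 0]], dtype=float)
    with_nan = m.copy()
    with_nan[3, 2] = np.nan
    # p_2 over observed rows is (1+1+0)/3; imputing shifts the coefficient
    # but the complete-data case must be reproduced exactly when nothing is missing
    assert kr20(m) == pytest.approx(cronbach_alpha(m), abs=1e-12)
    assert np.isfinite(kr20(with_nan))


# --- Spearman-Brown -------------------------------------------------------


def test_spearman_brown_values():
    assert spearman_brown(0.0) == 0.0
    assert spearman_brown(1.0) == 1.0
    assert spearman_brown(0.6) == pytest.approx(0.75)
    with pytest.raises(EstimationError):
        spearman_brown(-1.0)


@given(st.floats(min_value=-0.99, max_value=0.99))
@settings(max_examples=100, deadline=None)
def test_spearman_brown_monotone(r):
    assert spearman_brown(r + 0.01) > spearman_brown(r)


# --- split-half -----------------------------------------------------------


def _bimodal_cohort(n_half=10):
    """Deterministic cohort: half all-negative identifications, half all-benign."""
    return [make_session(f"n{i}", 240, 0) for i in range(n_half)] + [
        make_session(f"b{i}", 0, 240) for i in range(n_half)
    ]


def test_split_half_perfect_cohort_gives_one():
    sessions = _bimodal_cohort()
    assert split_half_oddeven(sessions) == pytest.approx(1.0)
    mean, ci, est = split_half_permutation(sessions, n_permutations=20, seed=0)
    assert mean == pytest.approx(1.0)
    assert ci == (pytest.approx(1.0), pytest.approx(1.0))


def test_split_half_permutation_reproducible(small_cohort):
    sessions = [s for s in small_cohort.sessions
                if score_session(s).retained]
    m1, ci1, e1 = split_half_permutation(sessions, n_permutations=50, seed=9)
    m2, ci2, e2 = split_half_permutation(sessions, n_permutations=50, seed=9)
    assert m1 == m2 and ci1 == ci2 and np.array_equal(e1, e2)
    m3, _, _ = split_half_permutation(sessions, n_permutations=50, seed=10)
    assert m1 != m3


def test_oddeven_close_to_permutation_mean(small_cohort):
    """Trials are exchangeable under the generative model, so the odd/even
    split is one draw from the permutation distribution."""
    sessions = [s for s in small_cohort.sessions if score_session(s).retained]
    oe = split_half_oddeven(sessions)
    mean, _, est = split_half_permutation(sessions, n_permutations=300, seed=1)
    assert abs(oe - mean) < max(4 * est.std(), 0.05)


def test_item_matrix_row_means_reproduce_index(small_cohort):
    """Cross-module oracle: per-person matrix means equal score_session indices."""
    results = [score_session(s) for s in small_cohort.sessions]
    retained = [s for s, r in zip(small_cohort.sessions, results) if r.retained]
    expected = [r.ab_index for r in results if r.retained]
    matrix = build_item_matrix(retained)
    assert matrix.row_means() == pytest.approx(expected)
    # unidentified presentations and only those are missing
    n_missing = int(np.isnan(matrix.data).sum())
    assert n_missing == sum(r.n_unidentified for r in results if r.retained)


# --- correlation ----------------------------------------------------------


def test_pearson_hand_computation():
    """x=(1,2,3,4), y=(2,1,4,3): cov/sds from the definition give r = 0.6."""
    res = pearson_with_test(np.array([1, 2, 3, 4]), np.array([2, 1, 4, 3]))
    assert res.r == pytest.approx(0.6)
    assert res.df == 2
    assert res.d == pytest.approx(2 * 0.6 / np.sqrt(1 - 0.36))


def test_pearson_identity_and_errors(rng):
    x = rng.normal(size=20)
    assert pearson_with_test(x, x).r == pytest.approx(1.0)
    with pytest.raises(EstimationError):
        pearson_with_test(x, np.zeros(20))
    with pytest.raises(EstimationError):
        pearson_with_test(x[:2], x[:2])


def test_r_to_d_printed_conversion():
    assert r_to_d(0.20) == pytest.approx(0.408, abs=5e-4)
    assert round(r_to_d(0.20), 2) == 0.41


# --- mediation ------------------------------------------------------------


def test_mediation_near_deterministic_chain(rng):
    """X -> M -> Y chain: a ~ 1, b = 1, c' = 0, indirect ~ 1."""
    x = rng.normal(size=100)
    m = x + 1e-4 * rng.normal(size=100)  # exact collinearity is rejected
    y = m.copy()
    res = mediate(x, m, y, n_boot=200, seed=0)
    assert res.a.coef == pytest.approx(1.0, abs=1e-6)
    assert res.b.coef == pytest.approx(1.0, abs=1e-6)
    assert res.c_prime.coef == pytest.approx(0.0, abs=1e-6)
    assert res.indirect == pytest.approx(1.0, abs=1e-6)


def test_mediation_collinear_raises(rng):
    x = rng.normal(size=50)
    with pytest.raises(EstimationError):
        mediate(x, x, rng.normal(size=50), n_boot=50, seed=0)


def test_mediation_ols_identity(rng):
    """c = c' + a*b holds to numerical precision for arbitrary data."""
    for _ in range(30):
        n = int(rng.integers(12, 120))
        x, m, y = rng.normal(size=(3, n))
        m = m + rng.uniform(-1, 1) * x
        y = y + rng.uniform(-1, 1) * x + rng.uniform(-1, 1) * m
        res = mediate(x, m, y, n_boot=10, seed=0)
        assert res.c.coef == pytest.approx(res.c_prime.coef + res.indirect, abs=1e-10)


def test_mediation_bootstrap_reproducible(rng):
    x, m, y = rng.normal(size=(3, 60))
    r1 = mediate(x, m, y, n_boot=500, seed=3)
    r2 = mediate(x, m, y, n_boot=500, seed=3)
    assert r1.ci == r2.ci and r1.indirect == r2.indirect
    assert r1.ci != mediate(x, m, y, n_boot=500, seed=4).ci


def test_mediation_requires_minimum_n(rng):
    x, m, y = rng.normal(size=(3, 5))
    with pytest.raises(EstimationError):
        mediate(x, m, y)
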