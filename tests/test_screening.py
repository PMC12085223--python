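"""Unit and property tests for the hybrid screening utilities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hifit.data import FeatureMatrix, Outcome
from hifit.screening import (
    UtilityTable,
    anomaly_scores,
    center_kernel,
    kpc_coefficient,
    polynomial_utility,
    rbf_kernel_matrix,
    select_features,
    utility_table,
)

# ---------------------------------------------------------------------------
# polynomial utility
# ---------------------------------------------------------------------------


def test_perfect_linear_fit_has_unit_utility():
    x = np.array([1.0, 2, 3, 4, 5])
    y = Outcome(2.0 * x)
    rho1, flag = polynomial_utility(x, y, M=1)
    assert rho1 == pytest.approx(1.0)
    assert flag == ""


def test_constant_outcome_returns_zero():
    x = np.random.default_rng(0).standard_normal(30)
    rho1, flag = polynomial_utility(x, Outcome(np.full(30, 3.7)), M=2)
    assert rho1 == 0.0
    assert flag == "constant_outcome"


def test_constant_feature_returns_zero_with_warning():
    y = Outcome(np.random.default_rng(1).standard_normal(30))
    with pytest.warns(UserWarning):
        rho1, flag = polynomial_utility(np.full(30, 2.0), y, M=2)
    assert rho1 == 0.0
    assert flag == "constant_feature"


def test_adjusted_r2_matches_normal_equations_oracle():
    """Order-1 fit against an explicit normal-equations solve."""
    x = np.array([1.0, 2, 3, 4, 5])
    yv = np.array([1.1, 1.9, 3.2, 3.9, 5.1])
    # oracle: solve (X'X) b = X'y directly, then the adjusted-R2 formula
    D = np.column_stack([np.ones(5), x])
    b = np.linalg.solve(D.T @ D, D.T @ yv)
    sse = np.sum((yv - D @ b) ** 2)
    sst = np.sum((yv - yv.mean()) ** 2)
    expected = 1 - (5 - 1) / (5 - 1 - 1) * sse / sst
    assert expected == pytest.approx(0.99046862589)  # frozen oracle value
    rho1, _ = polynomial_utility(x, Outcome(yv), M=1)
    assert rho1 == pytest.approx(expected, abs=1e-10)


def test_mcfadden_pseudo_r2_binary_outcome():
    rng = np.random.default_rng(7)
    x = rng.standard_normal(200)
    prob = 1 / (1 + np.exp(-1.5 * x))
    y = Outcome((rng.uniform(size=200) < prob).astype(float), kind="binary")
    rho1, _ = polynomial_utility(x, y, M=2)
    noise, _ = polynomial_utility(rng.standard_normal(200), y, M=2)
    assert 0 < rho1 <= 1
    assert noise < rho1


def test_separated_binary_feature_falls_back_to_ridge():
    x = np.concatenate([np.linspace(-3, -1, 15), np.linspace(1, 3, 15)])
    y = Outcome((x > 0).astype(float), kind="binary")
    rho1, flag = polynomial_utility(x, y, M=1)
    assert flag == "ridge_fallback"
    assert rho1 > 0.8  # near-perfect separation gives near-unit pseudo-R2


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------


def test_rbf_kernel_closed_forms():
    v = np.array([0.0, 1.3])
    K = rbf_kernel_matrix(v, bandwidth=1.0)
    assert K[0, 1] == pytest.approx(np.exp(-(1.3**2) / 2))
    const = rbf_kernel_matrix(np.full(6, 2.2), bandwidth=0.7)
    assert np.allclose(const, 1.0)
    rngK = rbf_kernel_matrix(np.random.default_rng(3).standard_normal(20), 1.5)
    assert np.allclose(np.diag(rngK), 1.0)
    assert np.allclose(rngK, rngK.T)
    with pytest.raises(ValueError):
        rbf_kernel_matrix(v, bandwidth=0.0)


def test_center_kernel_annihilates_constants_and_matches_hkh():
    rng = np.random.default_rng(5)
    assert np.allclose(center_kernel(np.ones((7, 7))), 0.0)
    K = rng.standard_normal((3, 3))
    K = K + K.T
    H = np.eye(3) - np.ones((3, 3)) / 3
    assert np.allclose(center_kernel(K), H @ K @ H, atol=1e-12)
    big = rbf_kernel_matrix(rng.standard_normal(40), 1.0)
    Kt = center_kernel(big)
    assert np.max(np.abs(Kt.sum(axis=0))) < 1e-10
    assert np.max(np.abs(Kt.sum(axis=1))) < 1e-10


# ---------------------------------------------------------------------------
# kernel partial correlation
# ---------------------------------------------------------------------------


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_kpc_bounded_on_random_inputs(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 40))
    x = rng.standard_normal(n)
    y = Outcome(rng.standard_normal(n))
    val = kpc_coefficient(x, y)
    assert 0.0 <= val <= 1.0


def test_kpc_orders_dependence():
    """Independent permutation scores lower than the identical signal."""
    rng = np.random.default_rng(11)
    x = rng.standard_normal(200)
    y = Outcome(x.copy())
    dependent = kpc_coefficient(x, y)
    independent = kpc_coefficient(rng.permutation(x), y)
    assert independent < dependent
    assert independent < 0.1


def test_kpc_constant_outcome_raises():
    with pytest.raises(ValueError, match="zero kernel variation"):
        kpc_coefficient(np.arange(10.0), Outcome(np.full(10, 1.0)))


def test_linear_kernel_kpc_approximates_adjusted_r2():
    rng = np.random.default_rng(23)
    n = 500
    x = rng.standard_normal(n)
    y = Outcome(x + 0.6 * rng.standard_normal(n))
    r2, _ = polynomial_utility(x, y, M=1)
    kpc = kpc_coefficient(x, y, kernel="linear")
    assert kpc == pytest.approx(r2, abs=0.05)


# ---------------------------------------------------------------------------
# utility table
# ---------------------------------------------------------------------------


def test_utility_table_matches_scalar_operations(linear_data):
    X, y = linear_data
    U = utility_table(X, y)
    for j in [0, 5, 11]:
        rho1, _ = polynomial_utility(X.column(j), y, M=2)
        assert U.rho1[j] == pytest.approx(rho1, abs=1e-9)
        assert U.rho2[j] == pytest.approx(
            kpc_coefficient(X.column(j), y), abs=1e-9
        )


def test_utility_table_strong_signal_attains_max(rng):
    n, p = 300, 3
    V = rng.standard_normal((n, p))
    y = Outcome(2.0 * V[:, 0] + 0.3 * rng.standard_normal(n))
    U = utility_table(FeatureMatrix(V, ["a", "b", "c"]), y)
    assert np.argmax(U.rho1) == 0
    assert np.argmax(U.rho2) == 0


def test_utility_table_duplicate_columns_get_identical_rows(rng):
    n = 60
    col = rng.standard_normal(n)
    V = np.column_stack([col, rng.standard_normal(n), col])
    y = Outcome(col + 0.5 * rng.standard_normal(n))
    U = utility_table(FeatureMatrix(V, ["a", "b", "a2"]), y)
    assert U.rho1[0] == pytest.approx(U.rho1[2], abs=1e-12)
    assert U.rho2[0] == pytest.approx(U.rho2[2], abs=1e-12)


def test_utility_table_flags_constant_feature_without_aborting(rng):
    V = rng.standard_normal((50, 3))
    V[:, 1] = 4.0
    y = Outcome(V[:, 0] + 0.1 * rng.standard_normal(50))
    U = utility_table(FeatureMatrix(V, ["a", "const", "c"]), y)
    assert U.flags[1] == "constant_feature"
    assert U.rho1[1] == 0.0 and U.rho2[1] == 0.0
    assert U.rho1[0] > 0.5


# ---------------------------------------------------------------------------
# isolation-forest fusion
# ---------------------------------------------------------------------------


def _mini_isolation_forest(points, n_trees, psi, seed):
    """Independent brute-force isolation forest used as an oracle."""
    rng = np.random.default_rng(seed)

    def c(m):
        if m <= 1:
            return 0.0
        h = np.sum(1.0 / np.arange(1, m))  # harmonic number H(m-1)+... via H(m-1)
        hm1 = np.sum(1.0 / np.arange(1, m))
        return 2.0 * (np.log(m - 1) + np.euler_gamma) - 2.0 * (m - 1) / m

    def grow(idx, depth, limit):
        if depth >= limit or len(idx) <= 1:
            return ("leaf", len(idx))
        sub = points[idx]
        spans = sub.max(axis=0) - sub.min(axis=0)
        live = np.flatnonzero(spans > 0)
        if len(live) == 0:
            return ("leaf", len(idx))
        q = rng.choice(live)
        split = rng.uniform(sub[:, q].min(), sub[:, q].max())
        left = idx[sub[:, q] < split]
        right = idx[sub[:, q] >= split]
        if len(left) == 0 or len(right) == 0:
            return ("leaf", len(idx))
        return ("node", q, split, grow(left, depth + 1, limit), grow(right, depth + 1, limit))

    def path(tree, x, depth=0):
        if tree[0] == "leaf":
            return depth + c(tree[1])
        _, q, split, lt, rt = tree
        return path(lt if x[q] < split else rt, x, depth + 1)

    limit = int(np.ceil(np.log2(psi)))
    trees = [
        grow(rng.choice(len(points), size=psi, replace=False), 0, limit)
        for _ in range(n_trees)
    ]
    depths = np.array([[path(t, x) for t in trees] for x in points])
    return 2.0 ** (-depths.mean(axis=1) / c(psi))


def _table(pts):
    return UtilityTable(
        pts[:, 0], pts[:, 1], 2, 1e-3, [f"f{i}" for i in range(len(pts))]
    )


def test_identical_utility_rows_score_equally():
    pts = np.tile([[0.2, 0.3]], (50, 1))
    s = anomaly_scores(_table(pts), seed=0)
    assert np.allclose(s, s[0])


def test_planted_outlier_attains_maximum_score():
    rng = np.random.default_rng(3)
    pts = np.vstack([rng.normal(0.0, 0.02, size=(200, 2)), [[0.9, 0.9]]])
    pts = np.clip(pts, 0, 1)
    s = anomaly_scores(_table(pts), B=200, seed=5)
    assert np.argmax(s) == 200
    assert np.all((s >= 0) & (s <= 1))
    # independent implementation agrees on the outlier and broadly on ranks
    oracle = _mini_isolation_forest(pts, n_trees=100, psi=min(256, len(pts)), seed=9)
    assert np.argmax(oracle) == 200
    from scipy.stats import spearmanr

    assert spearmanr(s, oracle).statistic > 0.7


def test_anomaly_scores_invariant_to_feature_order():
    rng = np.random.default_rng(17)
    pts = rng.uniform(0, 0.3, size=(80, 2))
    s1 = anomaly_scores(_table(pts), seed=4)
    perm = rng.permutation(80)
    s2 = anomaly_scores(_table(pts[perm]), seed=4)
    assert np.allclose(s1[perm], s2)


def test_anomaly_scores_rejects_degenerate_sizes():
    with pytest.raises(ValueError):
        anomaly_scores(_table(np.array([[0.1, 0.1]])))
    with pytest.raises(ValueError):
        anomaly_scores(_table(np.zeros((5, 2))), psi=10)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "scores,tau,expected",
    [
        ([0.4, 0.55, 0.7], 0.0, [0, 1, 2]),
        ([0.4, 0.55, 0.7], 1.1, []),
        ([0.4, 0.55, 0.7], 0.55, [1, 2]),  # inclusive threshold
    ],
)
def test_select_features_thresholding(scores, tau, expected):
    assert select_features(np.array(scores), tau).tolist() == expected
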