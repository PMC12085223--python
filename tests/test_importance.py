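"""Tests for the permutation importance test and refinement."""

import numpy as np
import pytest

from hifit.data import FeatureMatrix, Outcome
from hifit.importance import (
    ImportanceResult,
    SplitPlan,
    permfit,
    permfit_test,
    permute_feature,
    refine,
)
from hifit.models import BackendSpec, fit


def test_permute_feature_preserves_multiset_and_other_columns(rng):
    V = rng.standard_normal((40, 5))
    X = FeatureMatrix(V, list("abcde"))
    Xp = permute_feature(X, 2, np.random.default_rng(1))
    assert np.array_equal(np.sort(Xp.values[:, 2]), np.sort(V[:, 2]))
    others = [0, 1, 3, 4]
    assert np.array_equal(Xp.values[:, others], V[:, others])
    # fixed seed -> identical output
    Xp2 = permute_feature(X, 2, np.random.default_rng(1))
    assert np.array_equal(Xp.values, Xp2.values)


def test_permute_feature_single_row_is_identity():
    V = np.array([[1.0, 2.0]])
    assert np.array_equal(permute_feature(V, 0, np.random.default_rng(0)), V)


def _ignoring_model(feature_names):
    """A fitted-model stand-in that provably ignores every column but the first."""

    class _Est:
        def predict(self, V):
            return 3.0 * V[:, 0]

    from hifit.models import FittedModel

    return FittedModel(
        backend=BackendSpec("xgboost"),
        feature_names=list(feature_names),
        kind="continuous",
        _predictors=[_Est()],
    )


def test_score_exactly_zero_for_ignored_feature(rng):
    n = 50
    V = rng.standard_normal((n, 3))
    X = FeatureMatrix(V, ["a", "b", "c"])
    y = Outcome(3.0 * V[:, 0])
    model = _ignoring_model(X.feature_names)
    res = permfit_test(model, (X, y), rng=np.random.default_rng(0))
    assert res.lambda_hat[1] == 0.0 and res.lambda_hat[2] == 0.0
    assert res.p[1] == 1.0 and res.p[2] == 1.0
    assert res.lambda_hat[0] > 0  # the used feature hurts when permuted


def test_score_invariant_to_unseen_columns(rng):
    n = 60
    V = rng.standard_normal((n, 2))
    y = Outcome(3.0 * V[:, 0] + 0.1 * rng.standard_normal(n))
    model = _ignoring_model(["a", "b"])
    X2 = FeatureMatrix(V, ["a", "b"])
    base = permfit_test(model, (X2, y), features=[0], rng=np.random.default_rng(5))
    # add a column the model never sees; scoring of column a is unchanged
    V3 = np.column_stack([V, rng.standard_normal(n)])
    X3 = FeatureMatrix(V3, ["a", "b", "z"])
    wide = permfit_test(model, (X3, y), features=[0], rng=np.random.default_rng(5))
    assert wide.lambda_hat[0] == pytest.approx(base.lambda_hat[0], abs=1e-12)


def test_untrained_feature_scores_zero_by_convention(rng):
    n = 40
    V = rng.standard_normal((n, 3))
    X = FeatureMatrix(V, ["a", "b", "extra"])
    y = Outcome(V[:, 0])
    model = _ignoring_model(["a", "b"])
    res = permfit_test(model, (X, y), rng=np.random.default_rng(0))
    assert not res.tested[2]
    assert res.lambda_hat[2] == 0.0 and res.p[2] == 1.0


def test_binary_loglik_contrast_detects_signal(rng):
    n = 400
    V = rng.standard_normal((n, 4))
    prob = 1 / (1 + np.exp(-(2.0 * V[:, 0])))
    X = FeatureMatrix(V, list("abcd"))
    y = Outcome((rng.uniform(size=n) < prob).astype(float), kind="binary")
    spec = BackendSpec("xgboost", {"n_estimators": 100}, seed=0)
    res = permfit(spec, X, y, plan=SplitPlan(mode="single_split", seed=0), seed=1)
    assert res.p[0] < 0.05
    assert res.lambda_hat[0] > max(res.lambda_hat[1:])


def test_more_permutation_passes_do_not_inflate_variance(rng):
    """Averaging over extra permutation draws shrinks the Monte-Carlo noise."""
    n = 300
    V = rng.standard_normal((n, 3))
    X = FeatureMatrix(V, list("abc"))
    y = Outcome(1.5 * V[:, 0] + rng.standard_normal(n))
    spec = BackendSpec("xgboost", {"n_estimators": 50}, seed=0)
    model = fit(spec, X, y)
    se1, se8 = [], []
    for s in range(8):
        r1 = permfit_test(model, (X, y), features=[0], n_perm=1, rng=np.random.default_rng(s))
        r8 = permfit_test(model, (X, y), features=[0], n_perm=8, rng=np.random.default_rng(s))
        se1.append(r1.se[0])
        se8.append(r8.se[0])
    assert np.mean(se8) <= np.mean(se1) * 1.05


@pytest.mark.parametrize(
    "pvals,alpha,expected",
    [
        ([1.0, 1.0, 1.0], 0.1, []),
        ([0.5, 0.2, 0.9], 1.0, [3, 7, 9]),
        ([0.05, 0.5, 0.09], 0.1, [3, 9]),
    ],
)
def test_refine_thresholds_p_values(pvals, alpha, expected):
    screened = [3, 7, 9]
    imp = ImportanceResult(
        feature_names=[f"f{j}" for j in screened],
        lambda_hat=np.zeros(3),
        se=np.zeros(3),
        z=np.zeros(3),
        p=np.array(pvals),
        n_validation=10,
    )
    assert refine(screened, imp, alpha=alpha).tolist() == expected


def test_refine_keeps_exempt_covariates():
    imp = ImportanceResult(["a", "b"], np.zeros(2), np.zeros(2), np.zeros(2),
                           np.array([0.9, 0.9]), 10)
    assert refine([0, 1], imp, alpha=0.1, exempt=[1]).tolist() == [1]


def test_empty_validation_set_raises(rng):
    model = _ignoring_model(["a"])
    X = FeatureMatrix(rng.standard_normal((10, 1)), ["a"])
    with pytest.raises(ValueError):
        permfit_test(model, (X.rows([]), Outcome(np.array([]))), rng=0)
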