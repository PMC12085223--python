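"""Uniform contract over the machine-learning backends.

Four backends are supported — RBF-kernel SVM, random forest, gradient-boosted
trees (XGBoost) and a bagged multilayer-perceptron ensemble — behind a single
fit/predict interface.  A fitted model remembers its training feature names:
prediction aligns columns by name, ignores extra columns and raises on missing
ones, so importance testing and cutoff selection are backend-agnostic.

Continuous outcomes predict the conditional mean; binary outcomes predict the
class-1 probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .data import FeatureMatrix, Outcome

__all__ = ["BackendSpec", "FittedModel", "fit", "predict", "BACKENDS"]

BACKENDS = ("svm_rbf", "random_forest", "xgboost", "ensemble_dnn")


@dataclass
class BackendSpec:
    """Backend name, hyperparameter overrides and RNG seed."""

    name: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in BACKENDS:
            raise ValueError(f"unknown backend {self.name!r}; choose from {BACKENDS}")


@dataclass
class FittedModel:
    backend: BackendSpec
    feature_names: list[str]
    kind: str  # outcome kind
    _predictors: list[Any]  # one estimator, or the surviving ensemble members

    def predict(self, X: FeatureMatrix | np.ndarray) -> np.ndarray:
        return predict(self, X)


def _median_gamma(V: np.ndarray, rng) -> float:
    """RBF gamma = 1/(2·σ²) with σ the median pairwise row distance."""
    n = V.shape[0]
    take = rng.choice(n, size=min(n, 300), replace=False)
    S = V[take]
    d2 = np.sum((S[:, None, :] - S[None, :, :]) ** 2, axis=-1)
    med = np.sqrt(np.median(d2[np.triu_indices(len(S), k=1)]))
    if med <= 0:
        return 1.0
    return 1.0 / (2.0 * med**2)


class _Standardized:
    """Wrap an estimator with x (and, for regression, y) standardization."""

    def __init__(self, est, x_mean, x_sd, y_mean=0.0, y_sd=1.0):
        self.est = est
        self.x_mean, self.x_sd = x_mean, x_sd
        self.y_mean, self.y_sd = y_mean, y_sd

    def _xt(self, V):
        return (V - self.x_mean) / self.x_sd

    def fit(self, V, yv):
        self.est.fit(self._xt(V), (yv - self.y_mean) / self.y_sd)
        return self

    def predict(self, V):
        return self.est.predict(self._xt(V)) * self.y_sd + self.y_mean

    def predict_proba(self, V):
        return self.est.predict_proba(self._xt(V))

    @property
    def loss_(self):
        return self.est.loss_


def _standardizer(V, yv, kind):
    x_mean = V.mean(axis=0)
    x_sd = V.std(axis=0)
    x_sd[x_sd == 0] = 1.0
    if kind == "continuous":
        y_sd = yv.std() or 1.0
        return x_mean, x_sd, yv.mean(), y_sd
    return x_mean, x_sd, 0.0, 1.0


def _fit_svm(V, yv, kind, params, seed):
    from sklearn.svm import SVC, SVR

    x_mean, x_sd, y_mean, y_sd = _standardizer(V, yv, kind)
    # 1/d on standardized inputs, the classical RBF-SVM default; pass
    # gamma="median" for the median-heuristic bandwidth instead
    gamma = params.get("gamma", 1.0 / V.shape[1])
    if gamma == "median":
        gamma = _median_gamma((V - x_mean) / x_sd, np.random.default_rng(seed))
    C = params.get("C", 1.0)
    if kind == "continuous":
        est = SVR(kernel="rbf", C=C, gamma=gamma)
    else:
        est = SVC(kernel="rbf", C=C, gamma=gamma, probability=True, random_state=seed)
    wrapped = _Standardized(est, x_mean, x_sd, y_mean, y_sd)
    wrapped.fit(V, yv)
    return [wrapped]


def _fit_rf(V, yv, kind, params, seed):
    from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

    n_estimators = params.get("n_estimators", 500)
    # mtry defaults follow the classical p/3 (regression) / sqrt(p) (classif.)
    if kind == "continuous":
        est = RandomForestRegressor(
            n_estimators=n_estimators,
            max_features=params.get("max_features", 1 / 3),
            random_state=seed,
            n_jobs=1,
        )
    else:
        est = RandomForestClassifier(
            n_estimators=n_estimators,
            max_features=params.get("max_features", "sqrt"),
            random_state=seed,
            n_jobs=1,
        )
    est.fit(V, yv)
    return [est]


def _fit_xgb(V, yv, kind, params, seed):
    import xgboost as xgb

    common = dict(
        n_estimators=params.get("n_estimators", 500),
        max_depth=params.get("max_depth", 3),
        learning_rate=params.get("learning_rate", 0.1),
        random_state=seed,
        n_jobs=1,
        verbosity=0,
        early_stopping_rounds=params.get("early_stopping_rounds", 20),
    )
    cls = xgb.XGBRegressor if kind == "continuous" else xgb.XGBClassifier
    est = cls(**common)
    # 10% internal holdout drives early stopping
    rng = np.random.default_rng(seed)
    n = len(yv)
    hold = rng.choice(n, size=max(2, n // 10), replace=False)
    mask = np.zeros(n, dtype=bool)
    mask[hold] = True
    if kind == "binary" and len(np.unique(yv[mask])) < 2:
        est.set_params(early_stopping_rounds=None)
        est.fit(V, yv)
    else:
        est.fit(V[~mask], yv[~mask], eval_set=[(V[mask], yv[mask])], verbose=False)
    return [est]


def _fit_mlp_ensemble(V, yv, kind, params, seed):
    """Bagged MLP ensemble: bootstrap rows, average predictions, drop members
    that diverge (non-finite loss or grossly off-scale validation error)."""
    from sklearn.neural_network import MLPClassifier, MLPRegressor

    n_members = params.get("n_members", 10)
    hidden = params.get("hidden_layer_sizes", (64, 32))
    solver = params.get("solver", "lbfgs")  # full-batch L-BFGS suits small nets
    max_iter = params.get("max_iter", 1000 if solver == "lbfgs" else 500)
    rng = np.random.default_rng(seed)
    n = len(yv)
    members = []
    y_var = np.var(yv) if kind == "continuous" else None
    x_mean, x_sd, y_mean, y_sd = _standardizer(V, yv, kind)
    for m in range(n_members):
        boot = rng.integers(0, n, size=n)
        if kind == "binary" and len(np.unique(yv[boot])) < 2:
            continue
        cls = MLPRegressor if kind == "continuous" else MLPClassifier
        extra = (
            {}
            if solver == "lbfgs"
            else {"early_stopping": True, "n_iter_no_change": 20}
        )
        est = _Standardized(
            cls(
                hidden_layer_sizes=hidden,
                solver=solver,
                max_iter=max_iter,
                random_state=int(rng.integers(0, 2**31)),
                **extra,
            ),
            x_mean,
            x_sd,
            y_mean,
            y_sd,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(V[boot], yv[boot])
        if not np.isfinite(est.loss_):
            continue
        if kind == "continuous" and y_var is not None and y_var > 0:
            oob = est.predict(V)
            # diverged member: worse than predicting the mean by 4x
            if np.mean((oob - yv) ** 2) > 4.0 * y_var:
                continue
        members.append(est)
    if len(members) < max(1, n_members // 2):
        raise RuntimeError(
            f"MLP ensemble failed to converge: {len(members)}/{n_members} members survived"
        )
    return members


_FITTERS = {
    "svm_rbf": _fit_svm,
    "random_forest": _fit_rf,
    "xgboost": _fit_xgb,
    "ensemble_dnn": _fit_mlp_ensemble,
}


def fit(spec: BackendSpec, X: FeatureMatrix, y: Outcome) -> FittedModel:
    """Train a backend; returns a model predicting E[y|x] or P(y=1|x)."""
    if X.n_samples != len(y):
        raise ValueError("X and y sample counts differ")
    V = X.values
    yv = y.values.astype(int) if y.kind == "binary" else y.values
    predictors = _FITTERS[spec.name](V, yv, y.kind, spec.hyperparameters, spec.seed)
    return FittedModel(
        backend=spec,
        feature_names=list(X.feature_names),
        kind=y.kind,
        _predictors=predictors,
    )


def _member_predict(est, V: np.ndarray, kind: str) -> np.ndarray:
    if kind == "binary" and hasattr(est, "predict_proba"):
        return est.predict_proba(V)[:, 1]
    return np.asarray(est.predict(V), dtype=float)


def predict(model: FittedModel, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Predict on new samples, aligning columns by training feature name."""
    if isinstance(X, FeatureMatrix):
        missing = [f for f in model.feature_names if f not in X.feature_names]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        pos = {f: i for i, f in enumerate(X.feature_names)}
        V = X.values[:, [pos[f] for f in model.feature_names]]
    else:
        V = np.asarray(X, dtype=float)
        if V.shape[1] != len(model.feature_names):
            raise ValueError(
                f"expected {len(model.feature_names)} columns, got {V.shape[1]}"
            )
    preds = np.mean(
        [_member_predict(est, V, model.kind) for est in model._predictors], axis=0
    )
    if model.kind == "binary":
        preds = np.clip(preds, 0.0, 1.0)
    return preds
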