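"""Permutation-based feature importance testing (PermFIT).

The importance score of feature j is the expected increase in prediction loss
when column j is replaced by a random permutation of itself:

    Λ_j = E[{y − f(x^(j))}² − {y − f(x)}²]          (continuous)

estimated on a validation set disjoint from the data that trained f̂.  The
per-sample contrasts Λ̂_ij give the mean Λ̂_j, its variance estimate, a z
statistic λ_j = Λ̂_j / se and a one-sided normal p-value.  For binary outcomes
the squared-error contrast is replaced by a negative binomial log-likelihood
contrast on clipped predicted probabilities.

Features that were never screened into the model carry score 0 and p = 1 by
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import FeatureMatrix, Outcome
from .models import BackendSpec, FittedModel, fit, predict

__all__ = [
    "ImportanceResult",
    "SplitPlan",
    "permute_feature",
    "permfit_test",
    "permfit",
    "refine",
    "per_sample_loss",
]

PROB_CLIP = 1e-6


@dataclass
class SplitPlan:
    """How to separate model training from importance scoring."""

    mode: Literal["single_split", "kfold"] = "kfold"
    train_fraction: float = 0.8
    K: int = 5
    seed: int = 0

    def folds(self, n: int) -> list[tuple[np.ndarray, np.ndarray]]:
        """(train_idx, validation_idx) pairs; validation sets partition 1..n
        in kfold mode and are a single held-out block in single_split mode."""
        rng = np.random.default_rng(self.seed)
        perm = rng.permutation(n)
        if self.mode == "single_split":
            cut = int(round(self.train_fraction * n))
            return [(np.sort(perm[:cut]), np.sort(perm[cut:]))]
        if self.mode != "kfold":
            raise ValueError(f"unknown split mode {self.mode!r}")
        folds = np.array_split(perm, self.K)
        out = []
        for k in range(self.K):
            val = np.sort(folds[k])
            tr = np.sort(np.concatenate([folds[i] for i in range(self.K) if i != k]))
            out.append((tr, val))
        return out


@dataclass
class ImportanceResult:
    """Per-feature permutation importance statistics."""

    feature_names: list[str]
    lambda_hat: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    n_validation: int
    tested: np.ndarray = field(default=None)  # bool mask: actually permuted

    def __post_init__(self) -> None:
        if self.tested is None:
            self.tested = np.ones(len(self.feature_names), dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_name": self.feature_names,
                "importance_score": self.lambda_hat,
                "se": self.se,
                "z": self.z,
                "p_value": self.p,
            }
        )


def permute_feature(X: FeatureMatrix | np.ndarray, j: int, rng) -> FeatureMatrix | np.ndarray:
    """Copy of X with column j replaced by a uniform permutation of itself."""
    if isinstance(X, FeatureMatrix):
        values = X.values.copy()
        values[:, j] = rng.permutation(values[:, j])
        return FeatureMatrix(values, list(X.feature_names), X.sample_ids)
    values = np.array(X, dtype=float, copy=True)
    values[:, j] = rng.permutation(values[:, j])
    return values


def per_sample_loss(y: np.ndarray, pred: np.ndarray, kind: str) -> np.ndarray:
    """Squared error (continuous) or negative Bernoulli log-likelihood (binary)."""
    if kind == "continuous":
        return (y - pred) ** 2
    p = np.clip(pred, PROB_CLIP, 1.0 - PROB_CLIP)
    return -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))


def _contrast_columns(
    model: FittedModel,
    V: np.ndarray,
    yv: np.ndarray,
    base_loss: np.ndarray,
    columns: Sequence[int],
    n_perm: int,
    rng,
) -> np.ndarray:
    """Per-sample loss increase when the given columns are jointly permuted,
    averaged over n_perm independent permutation passes."""
    kind = model.kind
    acc = np.zeros(len(yv))
    for _ in range(n_perm):
        Vp = V.copy()
        for c in columns:
            Vp[:, c] = rng.permutation(Vp[:, c])
        acc += per_sample_loss(yv, predict(model, Vp), kind) - base_loss
    return acc / n_perm


def _zp(lam_i: np.ndarray) -> tuple[float, float, float, float]:
    nv = len(lam_i)
    lam = float(lam_i.mean())
    var = float(np.mean((lam_i - lam) ** 2))
    se = float(np.sqrt(var / nv))
    if se > 0:
        z = lam / se
        p = float(stats.norm.sf(z))
    else:
        z = 0.0
        p = 1.0 if lam <= 0 else 0.0
    return lam, se, z, p


def permfit_test(
    model: FittedModel,
    validation: tuple[FeatureMatrix, Outcome],
    features: Sequence[int] | None = None,
    n_perm: int = 1,
    rng=None,
) -> ImportanceResult:
    """Score features of a fitted model on a held-out validation set.

    ``features`` indexes columns of the validation FeatureMatrix; columns the
    model was not trained on get score 0 / p 1 without permutation.
    """
    Xv, yv = validation
    if Xv.n_samples == 0 or len(yv) == 0:
        raise ValueError("validation set is empty")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if features is None:
        features = range(Xv.n_features)
    features = list(features)

    model_cols = {f: i for i, f in enumerate(model.feature_names)}
    pos = {f: i for i, f in enumerate(Xv.feature_names)}
    V = Xv.values[:, [pos[f] for f in model.feature_names]]
    yvec = yv.values
    base_loss = per_sample_loss(yvec, predict(model, V), model.kind)

    p_feat = len(features)
    lam = np.zeros(p_feat)
    se = np.zeros(p_feat)
    z = np.zeros(p_feat)
    pval = np.ones(p_feat)
    tested = np.zeros(p_feat, dtype=bool)
    names = []
    for k, j in enumerate(features):
        name = Xv.feature_names[j]
        names.append(name)
        if name not in model_cols:
            continue  # untrained feature: score 0, p 1 by convention
        tested[k] = True
        lam_i = _contrast_columns(
            model, V, yvec, base_loss, [model_cols[name]], n_perm, rng
        )
        lam[k], se[k], z[k], pval[k] = _zp(lam_i)
    return ImportanceResult(names, lam, se, z, pval, len(yvec), tested)


def permfit(
    spec: BackendSpec,
    X: FeatureMatrix,
    y: Outcome,
    features: Sequence[int] | None = None,
    plan: SplitPlan | None = None,
    n_perm: int = 1,
    seed: int = 0,
) -> ImportanceResult:
    """Full cross-fitting PermFIT: fit per fold, pool per-sample contrasts.

    With the default 5-fold plan every sample is scored exactly once by a
    model that never saw it; the pooled contrasts give one z-test per feature.
    """
    if plan is None:
        plan = SplitPlan(seed=seed)
    if features is None:
        features = range(X.n_features)
    features = list(features)
    rng = np.random.default_rng(seed)

    pooled: dict[int, list[np.ndarray]] = {j: [] for j in features}
    n_total = 0
    for tr_idx, val_idx in plan.folds(X.n_samples):
        model = fit(spec, X.rows(tr_idx), y.take(tr_idx))
        Xv, yv = X.rows(val_idx), y.take(val_idx)
        V = Xv.values[:, [Xv.feature_names.index(f) for f in model.feature_names]]
        base_loss = per_sample_loss(yv.values, predict(model, V), model.kind)
        n_total += len(val_idx)
        cols = {f: i for i, f in enumerate(model.feature_names)}
        for j in features:
            name = X.feature_names[j]
            if name not in cols:
                continue
            pooled[j].append(
                _contrast_columns(model, V, yv.values, base_loss, [cols[name]], n_perm, rng)
            )

    p_feat = len(features)
    lam = np.zeros(p_feat)
    se = np.zeros(p_feat)
    z = np.zeros(p_feat)
    pval = np.ones(p_feat)
    tested = np.zeros(p_feat, dtype=bool)
    names = [X.feature_names[j] for j in features]
    for k, j in enumerate(features):
        if not pooled[j]:
            continue
        tested[k] = True
        lam[k], se[k], z[k], pval[k] = _zp(np.concatenate(pooled[j]))
    return ImportanceResult(names, lam, se, z, pval, n_total, tested)


def refine(
    screened: Sequence[int],
    importance: ImportanceResult,
    alpha: float = 0.1,
    exempt: Sequence[int] = (),
    adjust: bool = False,
) -> np.ndarray:
    """Keep screened features with importance p < alpha (exempt ones always).

    ``screened`` and ``importance`` must be aligned: importance.p[k] is the
    p-value of screened[k].  With ``adjust`` the Benjamini–Hochberg corrected
    p-values are thresholded instead.
    """
    screened = list(screened)
    if len(screened) != len(importance.p):
        raise ValueError("importance result does not align with screened set")
    pvals = importance.p
    if adjust and len(pvals):
        from statsmodels.stats.multitest import multipletests

        pvals = multipletests(pvals, method="fdr_bh")[1]
    exempt_set = set(int(j) for j in exempt)
    keep = [
        j
        for j, p in zip(screened, pvals)
        if p < alpha or j in exempt_set
    ]
    return np.array(sorted(set(keep) | exempt_set), dtype=int)
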