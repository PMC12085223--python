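"""Data-driven selection of the anomaly-score cutoff τ.

Candidate cutoffs (default 0.5, 0.55, 0.6, 0.65, 0.7) stratify the features
with score ≥ τ0 into half-open bins [τ_{r−1}, τ_r); features at or above the
largest candidate form the always-retained top stratum.  A backend model is
fitted once on all features above τ0, and each bin's *set importance* — the
PermFIT contrast with the whole bin permuted jointly — is tested on held-out
data.  The lower edge of the lowest significant bin (p < 0.1) becomes the
cutoff, so that bin and every higher stratum are kept; if no bin is
significant the cutoff falls back to the largest candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import FeatureMatrix, Outcome
from .importance import SplitPlan, _contrast_columns, _zp, per_sample_loss
from .models import BackendSpec, FittedModel, fit, predict

__all__ = [
    "CutoffCandidates",
    "SetImportanceResult",
    "bin_features",
    "set_importance",
    "select_tau",
    "adaptive_cutoff",
]

DEFAULT_CANDIDATES = (0.5, 0.55, 0.6, 0.65, 0.7)


@dataclass
class CutoffCandidates:
    taus: tuple[float, ...] = DEFAULT_CANDIDATES

    def __post_init__(self) -> None:
        taus = tuple(float(t) for t in self.taus)
        if len(taus) < 2:
            raise ValueError("need at least two candidate cutoffs")
        if any(b <= a for a, b in zip(taus, taus[1:])):
            raise ValueError("candidates must be strictly increasing")
        if taus[0] < 0 or taus[-1] > 1:
            raise ValueError("candidates must lie in [0, 1]")
        self.taus = taus

    def __iter__(self):
        return iter(self.taus)

    def __len__(self) -> int:
        return len(self.taus)


@dataclass
class SetImportanceResult:
    """Per-bin set importance statistics and the chosen cutoff."""

    candidates: CutoffCandidates
    bins: list[np.ndarray]  # index sets for [τ_{r−1}, τ_r), r = 1..R
    top_stratum: np.ndarray  # indices with score ≥ τ_R
    scores: np.ndarray  # set importance per bin
    se: np.ndarray
    p: np.ndarray
    chosen_tau: float = float("nan")


def bin_features(
    scores: np.ndarray, candidates: CutoffCandidates | Sequence[float] = DEFAULT_CANDIDATES
) -> tuple[list[np.ndarray], np.ndarray]:
    """Assign features to the half-open candidate bins.

    Returns (bins, top_stratum): bins[r−1] = {j : scores_j ∈ [τ_{r−1}, τ_r)}
    and the top stratum holds scores ≥ τ_R.
    """
    if not isinstance(candidates, CutoffCandidates):
        candidates = CutoffCandidates(tuple(candidates))
    scores = np.asarray(scores, dtype=float)
    taus = candidates.taus
    bins = [
        np.flatnonzero((scores >= lo) & (scores < hi))
        for lo, hi in zip(taus[:-1], taus[1:])
    ]
    top = np.flatnonzero(scores >= taus[-1])
    return bins, top


def set_importance(
    model: FittedModel,
    validation: tuple[FeatureMatrix, Outcome],
    S_r: Sequence[int],
    n_perm: int = 1,
    rng=None,
) -> tuple[float, float, float]:
    """PermFIT contrast with every column of the bin permuted jointly.

    Each column gets its own independent permutation draw; an empty bin scores
    0 with p = 1.
    """
    S_r = list(S_r)
    if not S_r:
        return 0.0, 0.0, 1.0
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    Xv, yv = validation
    pos = {f: i for i, f in enumerate(Xv.feature_names)}
    V = Xv.values[:, [pos[f] for f in model.feature_names]]
    cols = {f: i for i, f in enumerate(model.feature_names)}
    columns = [cols[Xv.feature_names[j]] for j in S_r if Xv.feature_names[j] in cols]
    if not columns:
        return 0.0, 0.0, 1.0
    base_loss = per_sample_loss(yv.values, predict(model, V), model.kind)
    lam_i = _contrast_columns(model, V, yv.values, base_loss, columns, n_perm, rng)
    lam, se, _, p = _zp(lam_i)
    return lam, se, p


def select_tau(results: SetImportanceResult, alpha: float = 0.1) -> float:
    """Lowest candidate whose bin (scanning upward) is significant.

    tau = τ_{r*−1} for the smallest r* with p(S_r*) < alpha, so the significant
    bin and all higher strata are retained; with no significant bin, tau is the
    largest candidate (keep only the top stratum).
    """
    taus = results.candidates.taus
    for r, p in enumerate(results.p):
        if p < alpha:
            return taus[r]
    return taus[-1]


def adaptive_cutoff(
    scores: np.ndarray,
    X_train: FeatureMatrix,
    y_train: Outcome,
    spec: BackendSpec,
    candidates: CutoffCandidates | Sequence[float] = DEFAULT_CANDIDATES,
    alpha: float = 0.1,
    plan: SplitPlan | None = None,
    n_perm: int = 1,
    seed: int = 0,
) -> SetImportanceResult:
    """Choose τ on training data: fit the backend on all features above τ0,
    then score each candidate bin on a held-out part of the training set.

    Degenerate cases: if nothing reaches τ0 the cutoff is τ0 itself (empty
    selection downstream); bins are always all tested for diagnostics.
    """
    if not isinstance(candidates, CutoffCandidates):
        candidates = CutoffCandidates(tuple(candidates))
    if plan is None:
        plan = SplitPlan(mode="single_split", train_fraction=0.8, seed=seed)
    scores = np.asarray(scores, dtype=float)
    bins, top = bin_features(scores, candidates)
    result = SetImportanceResult(
        candidates=candidates,
        bins=bins,
        top_stratum=top,
        scores=np.zeros(len(bins)),
        se=np.zeros(len(bins)),
        p=np.ones(len(bins)),
    )
    pre = np.flatnonzero(scores >= candidates.taus[0])
    if len(pre) == 0:
        result.chosen_tau = candidates.taus[0]
        return result

    rng = np.random.default_rng(seed)
    Xp = X_train.subset(pre)
    # map original indices -> positions within the pre-screened matrix
    local = {int(j): k for k, j in enumerate(pre)}
    folds = plan.folds(X_train.n_samples)
    pooled: list[list[np.ndarray]] = [[] for _ in bins]
    for tr_idx, val_idx in folds:
        model = fit(spec, Xp.rows(tr_idx), y_train.take(tr_idx))
        Xv, yv = Xp.rows(val_idx), y_train.take(val_idx)
        V = Xv.values[:, [Xv.feature_names.index(f) for f in model.feature_names]]
        base_loss = per_sample_loss(yv.values, predict(model, V), model.kind)
        for r, S_r in enumerate(bins):
            columns = [local[int(j)] for j in S_r]
            if not columns:
                continue
            pooled[r].append(
                _contrast_columns(model, V, yv.values, base_loss, columns, n_perm, rng)
            )
    for r in range(len(bins)):
        if pooled[r]:
            result.scores[r], result.se[r], _, result.p[r] = _zp(
                np.concatenate(pooled[r])
            )
    result.chosen_tau = select_tau(result, alpha=alpha)
    return result
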