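"""Hybrid feature screening (HFS).

Each feature j receives a two-component marginal utility vector
``rho_j = (rho_j1, rho_j2)``:

* ``rho_j1`` — a parametric utility: the adjusted R² of an order-M polynomial
  least-squares fit (continuous outcome) or McFadden's pseudo-R²
  ``1 - LL_j / LL_0`` from a logistic fit with monomial terms (binary outcome).
* ``rho_j2`` — the kernel partial correlation (KPC): a ridge-regularised
  trace ratio ``tr(Oᵀ K̃_y O) / tr(K̃_y)`` with ``O = K̃_j (K̃_j + n·δ·I)⁻¹``
  between centered RBF kernel matrices of the feature and the outcome.

The p utility vectors are then scored with an isolation forest fitted on the
p points in the (rho1, rho2) plane; under the sure-screening sparsity
assumption the noise features form a dense bulk and the important features are
anomalies, so a higher anomaly score ``s ∈ [0, 1]`` flags a stronger candidate.
Features with ``s ≥ τ`` form the screened set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import special
from sklearn.ensemble import IsolationForest

from .data import FeatureMatrix, Outcome

__all__ = [
    "UtilityTable",
    "ScreeningResult",
    "polynomial_utility",
    "rbf_kernel_matrix",
    "center_kernel",
    "kpc_coefficient",
    "utility_table",
    "anomaly_scores",
    "select_features",
    "median_bandwidth",
]

DEFAULT_M = 2
DEFAULT_DELTA = 1e-3
DEFAULT_TREES = 100
LOGISTIC_RIDGE = 1e-6


@dataclass
class UtilityTable:
    """Per-feature marginal utilities: parametric (rho1) and kernel (rho2)."""

    rho1: np.ndarray
    rho2: np.ndarray
    M: int
    delta: float
    feature_names: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)  # "" or a per-feature note

    def __post_init__(self) -> None:
        self.rho1 = np.asarray(self.rho1, dtype=float)
        self.rho2 = np.asarray(self.rho2, dtype=float)
        if self.rho1.shape != self.rho2.shape:
            raise ValueError("rho1 and rho2 must have equal length")
        if not self.flags:
            self.flags = [""] * len(self.rho1)

    def __len__(self) -> int:
        return len(self.rho1)

    def points(self) -> np.ndarray:
        """p x 2 array of (rho1 floored at 0, rho2) for anomaly scoring.

        Adjusted R² can be slightly negative for pure-noise features; flooring
        at zero keeps both axes oriented so that large means "associated".
        """
        return np.column_stack([np.maximum(self.rho1, 0.0), self.rho2])


@dataclass
class ScreeningResult:
    """Anomaly scores, the applied cutoff and the selected feature set."""

    scores: np.ndarray
    tau: float
    selected: np.ndarray  # integer indices, input order
    utility: UtilityTable
    iforest_params: tuple[int, int]  # (B trees, psi subsample)

    @property
    def selected_names(self) -> list[str]:
        return [self.utility.feature_names[j] for j in self.selected]


# ---------------------------------------------------------------------------
# parametric utility
# ---------------------------------------------------------------------------

def polynomial_utility(x: np.ndarray, y: Outcome, M: int = DEFAULT_M) -> tuple[float, str]:
    """Marginal polynomial-model utility of one feature.

    Continuous outcome: adjusted R² of the least-squares fit of y on
    (1, x, …, x^M).  Binary outcome: McFadden's pseudo-R², 1 − LL_M / LL_0,
    from the analogous logistic fit.

    Returns ``(rho1, flag)`` where flag is "" or a short diagnostic note.
    Degenerate predictors yield 0 with a warning rather than raising.
    """
    x = np.asarray(x, dtype=float)
    yv = y.values
    n = len(x)
    if len(yv) != n:
        raise ValueError("x and y length mismatch")
    if M < 1:
        raise ValueError("polynomial order M must be >= 1")
    if n <= M + 1:
        raise ValueError(f"need n > M + 1 samples (n={n}, M={M})")

    if np.ptp(x) == 0.0:
        warnings.warn("constant feature: utility set to 0", stacklevel=2)
        return 0.0, "constant_feature"

    # centre/scale for conditioning only; the polynomial column span (hence
    # R² and the logistic likelihood) is invariant to this affine map
    xs = (x - x.mean()) / x.std()
    design = np.vander(xs, M + 1, increasing=True)

    if y.kind == "continuous":
        if np.ptp(yv) == 0.0:
            return 0.0, "constant_outcome"
        sst = float(np.sum((yv - yv.mean()) ** 2))
        coef, *_ = np.linalg.lstsq(design, yv, rcond=None)
        sse = float(np.sum((yv - design @ coef) ** 2))
        rho1 = 1.0 - (n - 1) / (n - M - 1) * sse / sst
        return rho1, ""
    return _mcfadden(design, yv)


def _mcfadden(design: np.ndarray, yv: np.ndarray) -> tuple[float, str]:
    """McFadden pseudo-R² for a logistic fit, ridge fallback on separation."""
    import statsmodels.api as sm

    n = len(yv)
    pbar = yv.mean()
    ll0 = n * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar))
    flag = ""
    llj = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(yv, design).fit(disp=0, maxiter=200)
            if res.mle_retvals.get("converged", False) and np.isfinite(res.llf):
                llj = float(res.llf)
        except Exception:
            pass
    if not np.isfinite(llj):
        # (quasi-)separation or non-convergence: small-L2 fallback
        from sklearn.linear_model import LogisticRegression

        flag = "ridge_fallback"
        clf = LogisticRegression(C=1.0 / (n * LOGISTIC_RIDGE), max_iter=1000)
        clf.fit(design[:, 1:], yv)
        prob = np.clip(clf.predict_proba(design[:, 1:])[:, 1], 1e-12, 1 - 1e-12)
        llj = float(np.sum(yv * np.log(prob) + (1 - yv) * np.log(1 - prob)))
    return 1.0 - llj / ll0, flag


# ---------------------------------------------------------------------------
# kernel utility
# ---------------------------------------------------------------------------

def median_bandwidth(v: np.ndarray) -> float:
    """Median heuristic: the median of all pairwise absolute differences.

    Falls back to the mean distance, then to 1.0, when the median is zero
    (e.g. binary vectors where most pairs coincide).
    """
    v = np.asarray(v, dtype=float)
    diffs = np.abs(v[:, None] - v[None, :])
    tri = diffs[np.triu_indices(len(v), k=1)]
    bw = float(np.median(tri))
    if bw <= 0.0:
        bw = float(np.mean(tri))
    if bw <= 0.0:
        bw = 1.0
    return bw


def rbf_kernel_matrix(v: np.ndarray, bandwidth: float = 1.0) -> np.ndarray:
    """Gaussian kernel matrix K[k, l] = exp(−(v_k − v_l)² / (2·bandwidth²))."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("kernel input contains non-finite entries")
    d = v[:, None] - v[None, :]
    return np.exp(-(d**2) / (2.0 * bandwidth**2))


def center_kernel(K: np.ndarray) -> np.ndarray:
    """Double-centering K̃ = HKH with H = I − (1/n)·11ᵀ.

    Implemented by subtracting row/column means (algebraically identical to
    the triple product); all row and column sums of the result vanish.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be square")
    row = K.mean(axis=1, keepdims=True)
    col = K.mean(axis=0, keepdims=True)
    return K - row - col + K.mean()


def _outcome_kernel(y: Outcome, bandwidth: float | None) -> np.ndarray:
    yv = y.values
    if y.kind == "continuous":
        sd = yv.std()
        if sd == 0:
            raise ValueError("outcome has zero kernel variation")
        yv = (yv - yv.mean()) / sd
    bw = bandwidth if bandwidth is not None else median_bandwidth(yv)
    return rbf_kernel_matrix(yv, bw)


def kpc_coefficient(
    x: np.ndarray,
    y: Outcome,
    delta: float = DEFAULT_DELTA,
    kernel: str = "rbf",
    bandwidth: float | None = None,
) -> float:
    """Empirical kernel partial correlation between a feature and the outcome.

    rho2 = tr(Oᵀ K̃_y O) / tr(K̃_y) with O = K̃_x (K̃_x + n·δ·I)⁻¹; the ridge
    operator has spectral norm ≤ 1 so the value lies in [0, 1].  With a linear
    kernel on both sides this approximates the adjusted R² of the order-1
    polynomial utility.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 samples")
    if len(y) != n:
        raise ValueError("x and y length mismatch")

    if kernel == "rbf":
        sd = x.std()
        xs = (x - x.mean()) / sd if sd > 0 else x - x.mean()
        bw = bandwidth if bandwidth is not None else median_bandwidth(xs)
        Kx = rbf_kernel_matrix(xs, bw)
        Ky = _outcome_kernel(y, bandwidth)
    elif kernel == "linear":
        Kx = np.outer(x, x)
        Ky = np.outer(y.values, y.values)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")

    Kxt = center_kernel(Kx)
    Kyt = center_kernel(Ky)
    try_ = float(np.trace(Kyt))
    if try_ <= 0:
        raise ValueError("outcome has zero kernel variation")
    O = np.linalg.solve(Kxt + n * delta * np.eye(n), Kxt)  # symmetric
    val = float(np.einsum("ij,ji->", O @ Kyt, O)) / try_
    return float(np.clip(val, 0.0, 1.0))


# ---------------------------------------------------------------------------
# full utility table (vectorised over features)
# ---------------------------------------------------------------------------

def utility_table(
    X: FeatureMatrix,
    y: Outcome,
    M: int = DEFAULT_M,
    delta: float = DEFAULT_DELTA,
    kernel: str = "rbf",
    chunk_size: int = 16,
) -> UtilityTable:
    """Compute (rho1, rho2) for every feature column.

    The KPC pass batches features into stacked kernel solves, which is the
    dominant cost (O(n³) per feature); results are identical to calling the
    scalar operations column by column and independent of evaluation order.
    A degenerate feature is flagged and scored 0 instead of aborting the scan.
    """
    n, p = X.n_samples, X.n_features
    yv = y.values
    rho1 = np.zeros(p)
    rho2 = np.zeros(p)
    flags = [""] * p

    for j in range(p):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho1[j], flags[j] = polynomial_utility(X.column(j), y, M=M)

    Kyt = center_kernel(_outcome_kernel(y, None))
    try_ = float(np.trace(Kyt))
    if try_ <= 0:
        raise ValueError("outcome has zero kernel variation")

    sd = X.values.std(axis=0)
    live = np.flatnonzero(sd > 0)
    for j in np.flatnonzero(sd == 0):
        flags[j] = flags[j] or "constant_feature"
    Xs = np.zeros_like(X.values)
    Xs[:, live] = (X.values[:, live] - X.values[:, live].mean(axis=0)) / sd[live]

    if kernel != "rbf":
        for j in live:
            rho2[j] = kpc_coefficient(X.column(j), y, delta=delta, kernel=kernel)
        return UtilityTable(rho1, rho2, M, delta, list(X.feature_names), flags)

    eye = n * delta * np.eye(n)
    for start in range(0, len(live), chunk_size):
        idx = live[start : start + chunk_size]
        cols = Xs[:, idx]  # (n, k)
        d = cols[:, None, :] - cols[None, :, :]  # (n, n, k)
        ad = np.abs(d)
        iu = np.triu_indices(n, k=1)
        bw = np.median(ad[iu[0], iu[1], :], axis=0)
        bw[bw <= 0] = 1.0
        K = np.exp(-(d**2) / (2.0 * bw**2)).transpose(2, 0, 1)  # (k, n, n)
        row = K.mean(axis=2, keepdims=True)
        col = K.mean(axis=1, keepdims=True)
        Kt = K - row - col + K.mean(axis=(1, 2), keepdims=True)
        O = np.linalg.solve(Kt + eye, Kt)
        vals = np.einsum("bij,jk,bki->b", O, Kyt, O, optimize=True) / try_
        rho2[idx] = np.clip(vals, 0.0, 1.0)

    return UtilityTable(rho1, rho2, M, delta, list(X.feature_names), flags)


# ---------------------------------------------------------------------------
# isolation-forest fusion
# ---------------------------------------------------------------------------

def average_path_length(psi: int) -> float:
    """c(ψ) = 2·H(ψ−1) − 2(ψ−1)/ψ, the BST average unsuccessful-search depth."""
    if psi <= 1:
        return 1.0
    return float(2.0 * (special.digamma(psi) + np.euler_gamma) - 2.0 * (psi - 1) / psi)


def anomaly_scores(
    U: UtilityTable,
    B: int = DEFAULT_TREES,
    psi: int | None = None,
    seed: int | None = 0,
) -> np.ndarray:
    """Isolation-forest anomaly score of each feature's utility vector.

    Fits B isolation trees on the p points (max(rho1, 0), rho2); the score is
    s = 2^(−E[h]/c(ψ)) ∈ [0, 1], higher meaning more isolated, i.e. a stronger
    screening candidate.  Points are canonically pre-sorted before the forest
    is grown, so for a fixed seed the scores do not depend on feature order.

    Each tree sees the full feature cloud by default (psi = p, capped at 4096):
    the cloud has only p points and the selection rule compares scores with an
    absolute candidate grid, so subsampling would make the noise bulk look
    sparser than it is and push its scores across the grid's lower edge.
    """
    pts = U.points()
    p = len(pts)
    if p < 2:
        raise ValueError("anomaly scoring needs at least 2 features")
    if psi is None:
        psi = min(4096, p)
    if psi > p:
        raise ValueError(f"subsample size psi={psi} exceeds p={p}")
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    forest = IsolationForest(
        n_estimators=B, max_samples=psi, random_state=seed, contamination="auto"
    )
    forest.fit(pts[order])
    # sklearn's score_samples is the negated 2^(−E[h]/c(ψ)) statistic
    sorted_scores = -forest.score_samples(pts[order])
    scores = np.empty(p)
    scores[order] = sorted_scores
    return scores


def select_features(scores: np.ndarray, tau: float) -> np.ndarray:
    """Indices with score ≥ tau (inclusive), in input order."""
    scores = np.asarray(scores, dtype=float)
    return np.flatnonzero(scores >= tau)


def screen(
    X: FeatureMatrix,
    y: Outcome,
    tau: float = 0.5,
    M: int = DEFAULT_M,
    delta: float = DEFAULT_DELTA,
    kernel: str = "rbf",
    B: int = DEFAULT_TREES,
    psi: int | None = None,
    seed: int | None = 0,
) -> ScreeningResult:
    """One-call screening: utilities → anomaly scores → threshold at tau."""
    U = utility_table(X, y, M=M, delta=delta, kernel=kernel)
    s = anomaly_scores(U, B=B, psi=psi, seed=seed)
    if psi is None:
        psi = min(256, len(U))
    return ScreeningResult(
        scores=s,
        tau=tau,
        selected=select_features(s, tau),
        utility=U,
        iforest_params=(B, psi),
    )
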