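"""Synthetic data generators and evaluation metrics for the benchmark study.

The generators reproduce the study conditions used throughout the package's
validation: n = 500 samples, p ∈ {500, 1000, 10000} features with the first
10 driving the outcome, predictors drawn from a block-correlated multivariate
normal (or multinomial / Poisson log-normal variants), and two outcome models:

* linear:     y = Σ_{j≤10} β_j x_j + ε
* nonlinear:  y = Σ_{j≤4} 2·sin(2x_j) − Σ_{5≤j≤8} 2·log(2x_j² + 1)
              + x_9·exp(x_10) + ε

with ε ~ N(0,1) and β ~ U(1, 1.5) drawn once per scenario and held fixed
across Monte-Carlo replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .data import FeatureMatrix, Outcome

__all__ = [
    "SimulationScenario",
    "gen_design",
    "gen_outcome",
    "draw_beta",
    "evaluate_selection",
    "evaluate_prediction",
    "mean_rank",
    "train_test_split_indices",
    "run_benchmark",
]

N_IMPORTANT = 10


@dataclass
class SimulationScenario:
    """Generator settings for one simulated experiment."""

    scenario: Literal["linear", "nonlinear"] = "linear"
    n: int = 500
    p: int = 500
    design: Literal["mvn_block", "multinomial", "poisson_lognormal"] = "mvn_block"
    block_size: int = 10
    block_rho: float = 0.3
    split_ratio: float = 0.9  # training fraction of the 9:1 split
    seed: int = 0
    beta: np.ndarray | None = None  # drawn once if not supplied

    def __post_init__(self) -> None:
        if self.p < N_IMPORTANT:
            raise ValueError(f"p must be >= {N_IMPORTANT}")
        if not 0.0 <= self.block_rho < 1.0:
            raise ValueError("block_rho must be in [0, 1)")
        if self.beta is None:
            self.beta = draw_beta(self.seed)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (N_IMPORTANT,):
            raise ValueError(f"beta must have length {N_IMPORTANT}")

    @property
    def important(self) -> np.ndarray:
        return np.arange(N_IMPORTANT)


def draw_beta(seed: int) -> np.ndarray:
    """β ~ U(1, 1.5), drawn once per scenario and reused for every replicate."""
    return np.random.default_rng(seed).uniform(1.0, 1.5, N_IMPORTANT)


def _block_normal(n: int, p: int, block: int, rho: float, rng) -> np.ndarray:
    """Standard-normal marginals with exchangeable correlation rho per block.

    Uses the one-factor construction x = √rho·z_block + √(1−rho)·z_own, which
    yields exactly the block-equicorrelated covariance without a Cholesky.
    """
    z = rng.standard_normal((n, p))
    if rho == 0.0:
        return z
    n_blocks = int(np.ceil(p / block))
    shared = rng.standard_normal((n, n_blocks))
    shared_full = np.repeat(shared, block, axis=1)[:, :p]
    return np.sqrt(rho) * shared_full + np.sqrt(1.0 - rho) * z


def gen_design(
    n: int,
    p: int,
    design: str = "mvn_block",
    seed: int = 0,
    block_size: int = 10,
    block_rho: float = 0.3,
) -> FeatureMatrix:
    """Simulate the predictor matrix under one of the three design families."""
    if not 0.0 <= block_rho < 1.0:
        raise ValueError("block correlation must be in [0, 1) for a PSD block")
    rng = np.random.default_rng(seed)
    Z = _block_normal(n, p, block_size, block_rho, rng)
    if design == "mvn_block":
        values = Z
    elif design == "multinomial":
        # three ordered categories from the latent normal tertiles
        values = np.digitize(Z, [-0.4307273, 0.4307273]).astype(float)
    elif design == "poisson_lognormal":
        values = rng.poisson(np.exp(Z)).astype(float)
    else:
        raise ValueError(f"unknown design {design!r}")
    names = [f"x{j + 1}" for j in range(p)]
    return FeatureMatrix(values, names)


def gen_outcome(
    X: FeatureMatrix,
    scenario: str,
    beta: np.ndarray,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> Outcome:
    """Continuous outcome under the linear or nonlinear generating model."""
    V = X.values
    if X.n_features < N_IMPORTANT:
        raise ValueError(f"need at least {N_IMPORTANT} features")
    rng = np.random.default_rng(seed)
    eps = noise_sd * rng.standard_normal(X.n_samples)
    if scenario == "linear":
        signal = V[:, :N_IMPORTANT] @ np.asarray(beta, dtype=float)
    elif scenario == "nonlinear":
        signal = (
            2.0 * np.sin(2.0 * V[:, 0:4]).sum(axis=1)
            - 2.0 * np.log(2.0 * V[:, 4:8] ** 2 + 1.0).sum(axis=1)
            + V[:, 8] * np.exp(V[:, 9])
        )
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return Outcome(signal + eps, kind="continuous")


def simulate(scenario: SimulationScenario, replicate: int = 0) -> tuple[FeatureMatrix, Outcome]:
    """Generate one replicate (X, y); replicate index perturbs only the data seed."""
    data_seed = (scenario.seed * 100003 + 7919 * replicate + 1) % (2**31)
    X = gen_design(
        scenario.n,
        scenario.p,
        design=scenario.design,
        seed=data_seed,
        block_size=scenario.block_size,
        block_rho=scenario.block_rho,
    )
    y = gen_outcome(X, scenario.scenario, scenario.beta, seed=data_seed + 1)
    return X, y


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def evaluate_selection(
    selected: Sequence[int], important: Sequence[int] = tuple(range(N_IMPORTANT))
) -> tuple[float, float]:
    """(recall, precision) of a selected index set against the planted set.

    An empty selection has precision 0 by convention.
    """
    sel = set(int(j) for j in selected)
    imp = set(int(j) for j in important)
    hits = len(sel & imp)
    recall = hits / len(imp) if imp else 0.0
    precision = hits / len(sel) if sel else 0.0
    return recall, precision


def mean_rank(scores: np.ndarray, important: Sequence[int]) -> float:
    """Average rank (1 = best) of the planted features under a score vector."""
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    rank = np.empty(len(scores))
    rank[order] = np.arange(1, len(scores) + 1)
    return float(rank[list(important)].mean())


def evaluate_prediction(
    y_true: np.ndarray, y_pred: np.ndarray, kind: str = "continuous"
) -> dict[str, float]:
    """Held-out metrics: MSE/PCC (continuous) or accuracy/AUC (binary).

    A constant prediction vector has no defined correlation; PCC is reported
    as 0 with a flag.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/truth length mismatch")
    out: dict[str, float] = {}
    if kind == "continuous":
        out["mse"] = float(np.mean((y_true - y_pred) ** 2))
        if np.std(y_pred) == 0 or np.std(y_true) == 0:
            out["pcc"] = 0.0
            out["pcc_degenerate"] = 1.0
        else:
            out["pcc"] = float(np.corrcoef(y_true, y_pred)[0, 1])
    elif kind == "binary":
        from sklearn.metrics import roc_auc_score

        out["accuracy"] = float(np.mean((y_pred >= 0.5) == y_true))
        out["auc"] = float(roc_auc_score(y_true, y_pred))
    else:
        raise ValueError(f"unknown outcome kind {kind!r}")
    return out


def train_test_split_indices(n: int, split_ratio: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Random 9:1-style split; returns (train_idx, test_idx)."""
    perm = rng.permutation(n)
    n_train = int(round(split_ratio * n))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


# ---------------------------------------------------------------------------
# benchmark harness
# ---------------------------------------------------------------------------

def run_benchmark(
    scenarios: Sequence[SimulationScenario],
    backends: Sequence[str] = ("xgboost",),
    replicates: int = 20,
    seed: int = 0,
    variants: Sequence[str] = ("full", "screened", "refined"),
    alpha: float = 0.1,
    screen_kwargs: dict | None = None,
    backend_params: dict | None = None,
) -> pd.DataFrame:
    """Run the simulation study and return a tidy results table.

    For each replicate the data are split 9:1; each requested variant trains
    on the training part and is scored on the held-out part:

    * ``full``      — backend on all p features;
    * ``screened``  — backend on the HFS list with the adaptive cutoff (S-);
    * ``refined``   — backend on the permutation-test refined list (HF-).

    One row per (scenario, p, replicate, backend, variant) with selection and
    prediction metrics.  Replicate failures are recorded, not fatal.
    """
    from .pipeline import run_pipeline_arrays
    from .screening import anomaly_scores, utility_table

    sk = dict(screen_kwargs or {})
    need_screen = any(v in variants for v in ("screened", "refined"))
    rows: list[dict] = []
    for sc in scenarios:
        for rep in range(replicates):
            X, y = simulate(sc, replicate=rep)
            rng = np.random.default_rng((seed * 9973 + rep) % (2**31))
            tr, te = train_test_split_indices(sc.n, sc.split_ratio, rng)
            scores = None
            if need_screen:
                # screening is backend-independent: compute once per replicate
                U = utility_table(
                    X.rows(tr),
                    y.take(tr),
                    M=sk.get("M", 2),
                    delta=sk.get("delta", 1e-3),
                    kernel=sk.get("kernel", "rbf"),
                )
                scores = anomaly_scores(
                    U, B=sk.get("B", 100), psi=sk.get("psi"),
                    seed=(seed * 131 + rep) % (2**31),
                )
            for backend in backends:
                try:
                    res = run_pipeline_arrays(
                        X.rows(tr),
                        y.take(tr),
                        X.rows(te),
                        y.take(te),
                        backend=backend,
                        variants=variants,
                        alpha=alpha,
                        seed=(seed * 131 + rep) % (2**31),
                        screen_kwargs=screen_kwargs,
                        backend_params=backend_params,
                        scores=scores,
                    )
                except Exception as exc:  # pragma: no cover - defensive
                    rows.append(
                        {
                            "scenario": sc.scenario,
                            "p": sc.p,
                            "replicate": rep,
                            "backend": backend,
                            "variant": "error",
                            "error": str(exc),
                        }
                    )
                    continue
                for variant, info in res.items():
                    rec, prec = evaluate_selection(info["selected"], sc.important)
                    row = {
                        "scenario": sc.scenario,
                        "p": sc.p,
                        "replicate": rep,
                        "backend": backend,
                        "variant": variant,
                        "n_selected": len(info["selected"]),
                        "recall": rec,
                        "precision": prec,
                    }
                    row.update(info["metrics"])
                    rows.append(row)
    return pd.DataFrame(rows)
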