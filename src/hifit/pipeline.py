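"""End-to-end orchestration: screen → choose cutoff → test → refine → refit.

Two entry points:

* :func:`run_pipeline_arrays` — in-memory pipeline on a prepared train/test
  split; used by the simulation benchmark.
* :func:`run_hifit` — file-based pipeline driven by a :class:`RunConfig`,
  writing the screening table, importance table, final feature list,
  prediction metrics and a reproducibility manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cutoff import DEFAULT_CANDIDATES, adaptive_cutoff
from .data import FeatureMatrix, Outcome
from .importance import ImportanceResult, SplitPlan, permfit, refine
from .models import BackendSpec, fit, predict
from .screening import anomaly_scores, select_features, utility_table
from .simulate import evaluate_prediction

logger = logging.getLogger("hifit")

__all__ = ["RunConfig", "run_hifit", "run_pipeline_arrays"]


@dataclass
class RunConfig:
    """Serializable description of a full pipeline run."""

    features_path: str
    outcome_path: str | None = None  # defaults to a column of features_path
    outcome_column: str | None = None
    outcome_kind: str = "continuous"
    covariates_path: str | None = None  # always-kept clinical covariates
    features_as_rows: bool = False
    delimiter: str | None = None
    # screening
    M: int = 2
    delta: float = 1e-3
    kernel: str = "rbf"
    iforest_trees: int = 100
    iforest_psi: int | None = None
    # cutoff
    cutoff_candidates: tuple[float, ...] = DEFAULT_CANDIDATES
    cutoff_alpha: float = 0.1
    # testing
    backend: str = "xgboost"
    backend_params: dict = field(default_factory=dict)
    split_mode: str = "kfold"
    split_k: int = 5
    train_fraction: float = 0.8
    n_perm: int = 1
    alpha: float = 0.1
    adjust: bool = False
    test_fraction: float = 0.1  # held-out fraction for prediction metrics
    seed: int = 0
    output_dir: str = "hifit_output"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cutoff_candidates"] = list(self.cutoff_candidates)
        return d


def run_pipeline_arrays(
    X_train: FeatureMatrix,
    y_train: Outcome,
    X_test: FeatureMatrix,
    y_test: Outcome,
    backend: str = "xgboost",
    variants: Sequence[str] = ("full", "screened", "refined"),
    alpha: float = 0.1,
    seed: int = 0,
    screen_kwargs: dict | None = None,
    backend_params: dict | None = None,
    importance_plan: SplitPlan | None = None,
    n_perm: int = 1,
    scores: np.ndarray | None = None,
) -> dict[str, dict]:
    """Train the requested variants and score them on the held-out split.

    ``scores`` may carry precomputed anomaly scores for X_train's columns
    (screening does not depend on the backend, so a benchmark loop computes
    them once per replicate); otherwise screening runs here.
    Returns {variant: {"selected": original column indices, "metrics": {...}}}.
    """
    sk = dict(screen_kwargs or {})
    spec = BackendSpec(backend, dict(backend_params or {}), seed=seed)
    kind = y_train.kind
    out: dict[str, dict] = {}

    need_screen = any(v in variants for v in ("screened", "refined"))
    screened = None
    if need_screen:
        if scores is None:
            U = utility_table(
                X_train,
                y_train,
                M=sk.get("M", 2),
                delta=sk.get("delta", 1e-3),
                kernel=sk.get("kernel", "rbf"),
            )
            scores = anomaly_scores(U, B=sk.get("B", 100), psi=sk.get("psi"), seed=seed)
        cut = adaptive_cutoff(
            scores,
            X_train,
            y_train,
            spec,
            candidates=sk.get("candidates", DEFAULT_CANDIDATES),
            alpha=sk.get("cutoff_alpha", 0.1),
            plan=SplitPlan(mode="single_split", train_fraction=0.8, seed=seed),
            seed=seed,
        )
        screened = select_features(scores, cut.chosen_tau)
        if len(screened) == 0:
            screened = np.array([int(np.argmax(scores))])
            logger.warning(
                "empty screened set at tau=%.2f; keeping top-scoring feature",
                cut.chosen_tau,
            )

    if "full" in variants:
        model = fit(spec, X_train, y_train)
        out["full"] = {
            "selected": np.arange(X_train.n_features),
            "metrics": evaluate_prediction(y_test.values, predict(model, X_test), kind),
        }

    if "screened" in variants:
        Xs, Xs_te = X_train.subset(screened), X_test.subset(screened)
        model = fit(spec, Xs, y_train)
        out["screened"] = {
            "selected": screened,
            "metrics": evaluate_prediction(y_test.values, predict(model, Xs_te), kind),
        }

    if "refined" in variants:
        plan = importance_plan or SplitPlan(mode="kfold", K=5, seed=seed + 1)
        Xs = X_train.subset(screened)
        imp = permfit(spec, Xs, y_train, plan=plan, n_perm=n_perm, seed=seed + 1)
        final = refine(list(screened), imp, alpha=alpha)
        if len(final) == 0:
            # no feature survives: intercept-only fallback (training mean)
            mu = float(y_train.values.mean())
            preds = np.full(X_test.n_samples, mu)
            metrics = evaluate_prediction(y_test.values, preds, kind)
        else:
            Xf, Xf_te = X_train.subset(final), X_test.subset(final)
            model = fit(spec, Xf, y_train)
            metrics = evaluate_prediction(y_test.values, predict(model, Xf_te), kind)
        out["refined"] = {"selected": final, "metrics": metrics, "importance": imp}
    return out


def run_hifit(config: RunConfig, X: FeatureMatrix | None = None, y: Outcome | None = None) -> dict:
    """Full file-based pipeline; returns the result bundle and writes outputs.

    Clinical covariates (if given) bypass screening, are always in the model
    and are exempt from refinement.
    """
    from .io import load_feature_matrix, load_outcome, read_table, write_table

    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if X is None:
        drop = (config.outcome_column,) if config.outcome_column else ()
        X = load_feature_matrix(
            config.features_path,
            delimiter=config.delimiter,
            features_as_rows=config.features_as_rows,
            drop_columns=drop,
        )
    if y is None:
        if config.outcome_path:
            y = load_outcome(
                config.outcome_path,
                column=config.outcome_column,
                kind=config.outcome_kind,
                delimiter=config.delimiter,
            )
        else:
            df = read_table(config.features_path, config.delimiter)
            y = load_outcome(df, column=config.outcome_column, kind=config.outcome_kind)

    covariate_names: list[str] = []
    if config.covariates_path:
        covariate_names = [
            line.strip()
            for line in open(config.covariates_path)
            if line.strip() and not line.startswith("#")
        ]
        missing = [c for c in covariate_names if c not in X.feature_names]
        if missing:
            raise ValueError(f"covariates not in feature table: {missing}")

    rng = np.random.default_rng(config.seed)
    n = X.n_samples
    n_test = max(1, int(round(config.test_fraction * n)))
    perm = rng.permutation(n)
    te, tr = np.sort(perm[:n_test]), np.sort(perm[n_test:])
    X_train, y_train = X.rows(tr), y.take(tr)
    X_test, y_test = X.rows(te), y.take(te)

    cov_idx = [X.feature_names.index(c) for c in covariate_names]
    omics_idx = [j for j in range(X.n_features) if j not in set(cov_idx)]

    spec = BackendSpec(config.backend, dict(config.backend_params), seed=config.seed)

    # --- screening on the omics block only -------------------------------
    logger.info("screening %d features on %d training samples", len(omics_idx), len(tr))
    X_omics = X_train.subset(omics_idx)
    U = utility_table(X_omics, y_train, M=config.M, delta=config.delta, kernel=config.kernel)
    scores = anomaly_scores(U, B=config.iforest_trees, psi=config.iforest_psi, seed=config.seed)
    cut = adaptive_cutoff(
        scores,
        X_omics,
        y_train,
        spec,
        candidates=config.cutoff_candidates,
        alpha=config.cutoff_alpha,
        plan=SplitPlan(mode="single_split", train_fraction=0.8, seed=config.seed),
        seed=config.seed,
    )
    screened_local = select_features(scores, cut.chosen_tau)
    screened = [omics_idx[j] for j in screened_local]
    logger.info("tau=%.2f selects %d of %d features", cut.chosen_tau, len(screened), len(omics_idx))

    screen_df = pd.DataFrame(
        {
            "feature_name": X_omics.feature_names,
            "rho1": U.rho1,
            "rho2": U.rho2,
            "anomaly_score": scores,
            "selected": np.isin(np.arange(len(scores)), screened_local).astype(int),
            "flags": U.flags,
        }
    )
    write_table(screen_df, outdir / "screening.tsv")

    # --- importance testing on screened ∪ covariates ----------------------
    model_idx = sorted(set(screened) | set(cov_idx))
    if not model_idx:
        model_idx = [int(np.argmax(scores))]
        logger.warning("empty screened set; keeping the top-scoring feature")
    Xm = X_train.subset(model_idx)
    plan = SplitPlan(
        mode=config.split_mode,
        train_fraction=config.train_fraction,
        K=config.split_k,
        seed=config.seed,
    )
    imp = permfit(spec, Xm, y_train, plan=plan, n_perm=config.n_perm, seed=config.seed + 1)
    exempt = [model_idx.index(j) for j in cov_idx]
    final_local = refine(
        list(range(len(model_idx))), imp, alpha=config.alpha,
        exempt=exempt, adjust=config.adjust,
    )
    final = [model_idx[j] for j in final_local]

    imp_df = imp.to_frame()
    imp_df["selected_final"] = np.isin(np.arange(len(model_idx)), final_local).astype(int)
    write_table(imp_df, outdir / "importance.tsv")

    # --- final refit and held-out metrics ---------------------------------
    if not final:
        logger.warning("no feature survived refinement; falling back to covariates only")
        final = cov_idx
    if final:
        model = fit(spec, X_train.subset(final), y_train)
        preds = predict(model, X_test.subset(final))
    else:
        preds = np.full(X_test.n_samples, float(y_train.values.mean()))
    metrics = evaluate_prediction(y_test.values, preds, y.kind)

    final_names = [X.feature_names[j] for j in final]
    (outdir / "final_features.txt").write_text("\n".join(final_names) + "\n")
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "version": __version__,
        "n_samples": n,
        "n_features": X.n_features,
        "chosen_tau": cut.chosen_tau,
        "n_screened": len(screened),
        "n_final": len(final),
        "metrics": metrics,
        "runtime_seconds": round(time.time() - t0, 2),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return {
        "screening": screen_df,
        "importance": imp_df,
        "final_features": final_names,
        "metrics": metrics,
        "manifest": manifest,
        "chosen_tau": cut.chosen_tau,
    }
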