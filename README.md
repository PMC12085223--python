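# hifit

Hybrid feature screening and permutation importance testing for
high-dimensional biomarker identification.

## The problem

Omics tables (microbiome abundances, gene expression, …) routinely carry
hundreds to tens of thousands of candidate features for a few hundred
samples. Machine-learning models that could capture nonlinear
feature–outcome relationships overfit badly at that dimensionality, and
single-criterion marginal screens (Pearson/Spearman correlation, MIC, HSIC,
lasso paths) each miss the association types they were not built for.

`hifit` implements a two-stage pipeline for analysts who want both a
predictive model and defensible per-feature inference:

1. **Hybrid feature screening (HFS).** Every feature j gets a utility
   vector ρ_j = (ρ_j1, ρ_j2): the adjusted R² (or McFadden pseudo-R²) of an
   order-M polynomial fit, and the kernel partial correlation
   ρ̂_j2 = tr(O_jᵀ K̃_y O_j)/tr(K̃_y), O_j = K̃_j(K̃_j + nδI)⁻¹, between
   centered RBF kernel matrices. An isolation forest fitted on the p points
   scores each feature s(ρ_j, ψ) = 2^(−E[h]/c(ψ)) ∈ [0, 1]; under the
   sparsity assumption the noise bulk scores low and important features are
   anomalies. The screened set is Ŝ = {j : s(ρ_j, ψ) ≥ τ}, with τ chosen
   from the candidate grid (0.5, …, 0.7) by set-level permutation testing.
2. **Permutation importance refinement (PermFIT-style).** A backend model
   (RBF-SVM, random forest, XGBoost, or a bagged-MLP ensemble) is fitted on
   the screened features; each feature's importance
   Λ̂_j = mean_i [{y_i − f̂(x_i^(j))}² − {y_i − f̂(x_i)}²] (column j
   permuted) is tested with a one-sided z-statistic λ_j = Λ̂_j/se on
   held-out folds, and features with p < 0.1 form the final set used to
   refit the reporting model.

See `docs/methods.md` for formulas, defaults and limitations.

## Worked example

```python
import numpy as np
from hifit import (
    SimulationScenario, BackendSpec,
    screen, adaptive_cutoff, select_features, permfit, refine,
)
from hifit.simulate import evaluate_selection, simulate, train_test_split_indices

# 500 samples x 500 features; features 1-10 drive the outcome linearly
sc = SimulationScenario(scenario="linear", n=500, p=500, seed=0)
X, y = simulate(sc, replicate=0)
tr, te = train_test_split_indices(500, 0.9, np.random.default_rng(0))
Xtr, ytr = X.rows(tr), y.take(tr)

res = screen(Xtr, ytr, seed=0)                     # utilities + anomaly scores
spec = BackendSpec("xgboost", seed=0)
cut = adaptive_cutoff(res.scores, Xtr, ytr, spec, seed=0)
screened = select_features(res.scores, cut.chosen_tau)
imp = permfit(spec, Xtr.subset(screened), ytr, seed=1)
final = refine(list(screened), imp, alpha=0.1)

print("chosen tau:", cut.chosen_tau)
print("screened:", len(screened), "features; recall/precision:",
      evaluate_selection(screened))
print("refined :", len(final), "features; recall/precision:",
      evaluate_selection(final))
```

Output:

```
chosen tau: 0.5
screened: 59 features; recall/precision: (1.0, 0.1694915254237288)
refined : 18 features; recall/precision: (1.0, 0.5555555555555556)
```

In this replicate the adaptive cutoff is generous — a low score bin tests
significant, τ drops to 0.5 and the screened list carries 49 noise features
alongside all ten planted ones. The importance test then does its job:
refinement keeps every true biomarker and discards most impostors, tripling
precision. In other replicates the cutoff lands at 0.65–0.7 and the refined
list is exactly the planted set; averaged over replicates and backends the
refined precision is about 0.9 (see the reproduction script below).

The same pipeline runs from the shell on delimited tables
(`hifit run --features table.csv --outcome-column bmi_change ...`), with
subcommands `screen`, `cutoff`, `test`, `run` and `simulate`; clinical
covariates listed via `--covariates` bypass screening and are exempt from
refinement.

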