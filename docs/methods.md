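# Methods

`hifit` screens high-dimensional feature tables for outcome-associated
biomarkers and then subjects the survivors to a formal permutation importance
test under a flexible machine-learning model. This note records the model,
the defaults and the numerical choices, and what the simulation-based tests
do and do not establish.

## Hybrid marginal screening

For each feature `x_j` two marginal utilities are computed against the
outcome `y`:

* **Parametric utility `rho_j1`.** An order-`M` polynomial (generalised)
  linear model `E[y|x_j] = g⁻¹(β₀ + Σ_m β_m x_j^m)` is fitted per feature.
  For continuous outcomes `rho_j1` is the adjusted R²,
  `1 − (n−1)/(n−M−1) · SSE/SST`; for binary outcomes it is McFadden's
  pseudo-R², `1 − LL_M/LL_0`, with `LL_0` the intercept-only log-likelihood.
  Default `M = 2`: linear plus quadratic effects, in line with common
  differential-abundance practice. The predictor is internally standardized
  for conditioning only; both statistics are invariant to that affine map.

* **Kernel partial correlation `rho_j2`.** With centered kernel matrices
  `K̃ = HKH`, `H = I − (1/n)11ᵀ`, the empirical KPC is the trace ratio
  `tr(Oᵀ K̃_y O) / tr(K̃_y)` where `O = K̃_j (K̃_j + nδI)⁻¹`. The ridge
  operator has spectral norm below one, so `rho_j2 ∈ [0, 1]`. The kernel is
  the Gaussian RBF `exp(−(a−b)²/2σ²)`; with a linear kernel the statistic
  tracks the order-1 adjusted R² (verified to within 0.05 at n = 500 in the
  test suite), which is the sense in which the RBF version generalises the
  polynomial model to unbounded order.

Defaults that the formulae leave open:

| parameter | default | rationale |
| --- | --- | --- |
| ridge `δ` | `1e-3` | small enough not to shrink real signal, large enough to keep `K̃ + nδI` well conditioned at n ≈ 500 |
| kernel bandwidth `σ` | median pairwise distance (per feature, on z-scored values) | standard median heuristic; a unit-bandwidth option exists |
| standardization | features and continuous outcomes z-scored before kernels | kernels are scale-sensitive; the polynomial fit uses raw values (R² is scale-free) |

Degenerate inputs: a constant feature scores 0 with a `constant_feature`
flag (the scan never aborts for one bad column); a constant outcome is a
hard error. A logistic fit that fails to converge (separation) falls back to
a small-L2 (`1e-6`) ridge fit and flags the feature.

The KPC pass is the dominant cost, O(n³) per feature; features are processed
in batches of stacked kernel solves (`numpy` batched `solve` plus one batched
matrix product per chunk), ~28 ms per feature at n = 450 on one core. Results
are identical to the scalar definition and independent of evaluation order;
the only randomness anywhere in screening is the seeded isolation forest.

## Isolation-forest fusion and the screened set

The p utility vectors `(max(rho_j1, 0), rho_j2)` form a two-dimensional
cloud. Under the sure-screening sparsity assumption the noise features are a
dense bulk and important features are anomalies, so an isolation forest
(B = 100 trees) scores each feature `s_j = 2^(−E[h]/c(ψ))` with
`c(ψ) = 2H(ψ−1) − 2(ψ−1)/ψ`; `s_j ∈ [0, 1]`, higher = more isolated =
stronger candidate. `S^ = {j : s_j ≥ τ}` (inclusive threshold). Choices:

* **rho1 floor.** Adjusted R² can be slightly negative for noise; the raw
  value is stored but floored at 0 for fusion so that both axes orient
  "large = associated".
* **Subsample ψ.** Default `ψ = min(4096, p)` — each tree sees the whole
  feature cloud. The selection rule below compares scores against an
  *absolute* candidate grid, so the score scale matters: subsampling a
  1000-point cloud to 256 makes the bulk look sparser than it is and pushes
  roughly 10% of pure-noise features above the grid's lower edge (measured:
  105 vs 59 crossings at p = 1000), which destabilises the cutoff search.
* **Order canonicalisation.** Points are lexicographically pre-sorted before
  the forest is grown, so scores are invariant to feature order at a fixed
  seed.

## Adaptive cutoff

Candidates `(0.5, 0.55, 0.6, 0.65, 0.7)` stratify the features above 0.5
into half-open bins `[τ_{r−1}, τ_r)`; scores ≥ 0.7 form the always-kept top
stratum. One backend model is fitted on all features above 0.5 (80% of the
training samples; the remaining 20% score the bins). Each bin's *set
importance* is the permutation contrast with every bin column permuted
jointly (one independent draw per column); the z-test is the same as the
per-feature test below. Scanning bins upward, the first bin with p < 0.1
sets the cutoff at its lower edge, so that bin and everything above it are
kept; with no significant bin the cutoff falls back to the largest
candidate, keeping only the top stratum (the most conservative non-empty
choice — the procedure's definition leaves this case open).

**Known fragility (reproduced deliberately).** A fitted model — especially
an RBF-SVM or MLP, but to a lesser degree boosted trees — depends slightly
on *every* column it was trained on, including pure noise. Jointly permuting
a large bin of noise columns therefore produces a genuinely positive loss
contrast, and a large pure-noise bin can test significant well above the
nominal 10% rate. When that happens the cutoff drops to 0.5 and the screened
set inflates (occasionally to 60–115 features at p = 1000), which costs the
kernel-type backends ~0.3 held-out PCC in those replicates. The procedure is
implemented exactly as specified (fixed candidate grid, bin rule, p < 0.1),
so this behaviour is part of the method, not a bug; it is the main driver of
the spread in the reproduction numbers below. In the simulated scenarios the
ten planted features essentially always sit in the top stratum, so recall is
unaffected — only precision and downstream prediction accuracy suffer.

## Permutation importance test

For a model `f̂_T` trained on samples disjoint from a validation set of size
`n_V`, the importance of feature j is estimated by the per-sample contrasts

    Λ̂_ij = {y_i − f̂_T(x_i^(j))}² − {y_i − f̂_T(x_i)}²

(`x^(j)` = column j permuted), with `Λ̂_j` their mean,
`se = sqrt(mean[(Λ̂_ij − Λ̂_j)²]/n_V)`, `λ_j = Λ̂_j/se`, and a one-sided
upper-tail normal p-value (importance cannot be meaningfully negative under
the alternative). For binary outcomes the squared error is replaced by the
negative Bernoulli log-likelihood on probabilities clipped to
`[1e−6, 1−1e−6]`. A feature the model was never trained on scores 0 with
p = 1 by convention.

The default split plan is 5-fold cross-fitting: fit on four folds, score the
held-out fold, pool the per-sample contrasts — every sample is scored
exactly once by a model that never saw it, which roughly quintuples the
effective `n_V` relative to a single 80/20 split (the optional
`single_split` mode). One permutation pass (`n_perm = 1`) is the default —
the estimator is unbiased per pass — and extra passes only reduce
Monte-Carlo noise.

Refinement keeps screened features with p < 0.1 (no multiplicity adjustment
by default; Benjamini–Hochberg is available as a flag) and always retains
the declared clinical covariates. Because each retained noise feature is an
α-level event, the expected number of false survivors is about
`0.1 × (#noise features screened)` — the refined set's precision is
therefore governed mainly by how tight the screened set was.

## Backends

All four backends satisfy one contract: fit on named columns, predict the
conditional mean (continuous) or class-1 probability (binary),
deterministically for a fixed seed; prediction aligns columns by name,
ignores extras and raises on missing ones.

* **svm_rbf** — RBF-kernel SVM, cost 1, `γ = 1/d` on internally
  standardized inputs (the classical default of the reference R backend;
  the median heuristic measured ~0.06 PCC worse on the nonlinear scenario
  and remains available via `gamma="median"`). x and, for regression, y are
  standardized inside the backend.
* **random_forest** — 500 trees, `mtry = p/3` (regression) or `√p`
  (classification), the classical defaults.
* **xgboost** — 500 rounds, depth 3, learning rate 0.1, early stopping
  (20 rounds) on an internal 10% holdout.
* **ensemble_dnn** — 10 bagged multilayer perceptrons, hidden layers
  (64, 32), bootstrap rows, averaged predictions; members with non-finite
  loss or validation error worse than 4× the outcome variance are dropped,
  and fitting errors out if fewer than half survive. Full-batch L-BFGS is
  the default solver — at n ≈ 450 it is both more accurate and ~3× faster
  than early-stopped Adam, which remains available via the `solver`
  hyperparameter.

## Synthetic data

The generator reproduces the benchmark's study conditions: n = 500 samples,
p ∈ {500, 1000, …} features, exactly 10 important (indices 1–10),
`β ~ U(1, 1.5)` drawn once per scenario and frozen across replicates,
`ε ~ N(0, 1)`, 9:1 train/test splits. Predictors are standard-normal with
block-exchangeable correlation (block size 10, within-block ρ = 0.3 —
chosen as a realistic default; the one-factor construction gives the exact
equicorrelated covariance). Multinomial (latent-normal tertiles) and
Poisson log-normal (Poisson rates `exp(Z)`) variants are provided for
non-Gaussian designs. Outcomes:

    linear:     y = Σ_{j=1..10} β_j x_j + ε
    nonlinear:  y = Σ_{j=1..4} 2 sin(2x_j) − Σ_{j=5..8} 2 log(2x_j²+1)
                + x_9 exp(x_10) + ε

What the generator does *not* emulate: real omics features are
non-Gaussian, zero-inflated, compositional and library-size confounded, and
real effect sizes are far below β ≈ 1.25. A passing simulation suite
demonstrates that the machinery is correct and that the screening/refinement
logic behaves as designed under clean conditions — not that it will recover
biology at these rates in practice. One concrete consequence of the chosen
correlation default: with ρ = 0.3 inside the important block, even
interaction-only features acquire marginal linear signal, so *all* rankings
(either single utility, the fused score, even plain Pearson correlation) put
the planted features at the optimal mean rank in nearly every replicate;
comparative ranking claims are therefore ties under these conditions and the
tests assert the meaningful residue (near-optimal fused ranking, no loss
against a Pearson screener at equal list size).

## Problem sizes used in the checks

The test suite and the reproduction script run the full pipeline at
n = 500 and p ∈ {500, 1000} with 2–8 replicates per condition (the script
uses 4), a desk-scale choice of replicate count; all other conditions are
the study conditions above. Typical reproduction numbers: refined-set
precision ≈ 0.80–0.96 averaged over the XGBoost/SVM/MLP backends (the
spread across seeds tracks how often the cutoff fragility strikes);
screening cuts held-out MSE by ≈ 38–42% on average over backends;
screened-model PCC is ≈ 0.94–0.99 in linear cells, while nonlinear cells
range from ≈ 0.85 (XGBoost, clean replicates) down to ≈ 0.4 in
blowup-heavy kernel-backend cells.

## Limitations

* The adaptive cutoff's set test is anti-conservative for large noise bins
  (see above); on data where many noise features score just above 0.5 the
  screened set can inflate. Inspecting the per-bin p-values in the
  diagnostics output (`hifit cutoff`) is advisable before trusting a low τ.
* Marginal screening inherits the usual sure-screening caveat: a feature
  important only conditionally (masked marginally) can be missed; the
  block-correlation in the simulations partially hides this failure mode.
* The normal approximation for λ_j is asymptotic in n_V; with very small
  validation sets the p-values are rough.
* Kernel screening is O(n³) per feature; beyond n ≈ a few thousand a
  subsampled or low-rank kernel would be needed.
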