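# Methods

## Model

Selection is cast as a linear program over per-feature weights
`w ∈ [0,1]^p` and per-sample slacks `ξ ∈ ℝ₊^n`.  For a sample `x` of
class `j` and every rival class `j'`, the constraint

    Σ_i (|x_i − m_i^j| − |x_i − m_i^j'|) w_i − ξ ≤ −δ

requires the weighted L1 distance to the own-class centroid `m^j` to
beat the distance to the rival centroid by at least `δ`.  The objective
`Σ w_i + λ Σ ξ_k` trades sparsity against separation.  Features with
optimal weight above `τ` are selected; features in the user's fixed
subset carry the bound `w_f ≥ MinWeight`, which both guarantees their
selection (`MinWeight > τ`) and gives them nontrivial influence in the
weighted-centroid predictor.

Model assumptions worth keeping in mind:

- **Centroid adequacy.**  Classes are summarized by their per-feature
  means; heavily multimodal classes are not represented well.
- **Additive L1 geometry.**  Features act additively in the distance;
  the model has no interaction terms, which is also why independent
  synthetic features suffice to exercise every code path.
- **Already-normalized input.**  Values are consumed as given
  (e.g. RMA-normalized intensities).  There is no imputation — missing
  values are a hard construction error.

### One slack per sample

Each sample has a single slack shared across all of its rival-class
rows, matching the objective's `Σ_j Σ_k ξ_k` indexing (`n` slacks in
total, not `n·(c−1)`).  For binary problems the two readings coincide;
for `c > 2` the shared slack charges a sample once for its worst
violation rather than summing violations, and one constraint row is
emitted per (sample, rival) pair — the own centroid must beat *every*
rival.  Multi-class behaviour beyond this strictest-consistent reading
is intentionally unembellished, as the method's validation is binary.

### Feasibility and degeneracy

Slacks are unbounded above and enter every row of their sample with
coefficient −1, so the LP is feasible for every valid configuration;
`status = infeasible_config` exists only as a defensive contract.  On
data where no feature separates the classes, weights cost more than
slack and the optimum may be all-zero weights — returned as-is with a
warning, with an empty selection; prediction then degenerates to the
first-class tie-break (also warned).  Constant features get all-zero
constraint coefficients and unit objective cost, so the optimizer
drives them to zero without special-casing.

## Parameters

| parameter | default | units / range | role |
|---|---|---|---|
| `lam` (λ) | 1.0 | ≥ 0, dimensionless | price of one unit of slack; 0 makes slack free (all-zero optimum), large values force maximal separation |
| `min_weight` | 0.1 | (0, 1] | weight floor for fixed features; values > 1 would contradict `w ≤ 1` and are rejected at construction |
| `margin` (δ) | 1e-3 | expression-distance units | stands in for the strict "closer than" inequality, which an LP cannot express; keeps the all-zero weight vector out of the separable optimum |
| `select_threshold` (τ) | 1e-6 | (0, min_weight), < δ | positive-weight cutoff; strict `>` so exact zeros are never selected |
| `folds` / `repeats` | 5 / 30 | — | the evaluation protocol's defaults; repeat `r` is seeded `base_seed + r` |

λ and MinWeight have no published reference values; the defaults are
neutral choices (unit slack price; a floor an order of magnitude below
the weight cap) and are exposed everywhere (API and CLI), tunable by
cross-validation.  The margin is scale-dependent by construction —
doubling all expression values halves the weight mass needed — so a
`standardize` flag (per-feature z-score, sample sd, constant features
to zero) is provided for data on heterogeneous scales; it is **off** by
default because normalized matrices are the expected input.

## Evaluation protocol

Repeated stratified k-fold cross-validation.  Within a fold, centroids
and the LP see training samples only; the selected features are handed
to the downstream classifier (built-in: the weighted nearest-centroid
rule reusing the fold's LP weights; pluggable: any
`classifier(train_values, train_labels) → predict(test_values)`
callable, e.g. a scikit-learn estimator through `sklearn_classifier`).
Per repeat, fold predictions are **pooled** into one confusion table
before computing metrics — chosen over per-fold averaging because
pooled counting is the natural reading of stable three-decimal metrics
over many repeats, and it keeps small test folds from producing
undefined per-fold MCCs.  Stratification is used because the target
cohorts are imbalanced enough that unstratified folds can lose a class
entirely.

Balanced accuracy is `(Sn+Sp)/2`.  MCC is `NaN` whenever a denominator
factor vanishes; NaN is propagated, never replaced by 0, and NaN-mean
models rank last in model comparison.

## Synthetic data

The generator draws independent Gaussians: informative feature means
are `j · effect_size` for class `j` (so consecutive classes are
`effect_size` sd apart at `noise_sd = 1`), noise features have mean 0
everywhere.  Defaults (30 + 30 samples, 2 informative + 48 noise
features, effect size 10, unit noise) give a strongly separable
dataset on which the pipeline should recover exactly the informative
set and score MCC ≈ 1 — the regime the method's published validation
operates in.  What passing these tests does **not** show: robustness to
correlated features, batch effects, heavy-tailed microarray noise, or
`p ≫ n` at the 2×10⁴-feature scale (the LP itself scales to that size;
the test problems are kept small so the full suite runs in seconds).

Fixing one deliberately uninformative feature is the stress version of
the known-biomarker use case.  At the study conditions (10 generator
seeds, 5 repeats of 5-fold CV) the mean MCC shift against the
unconstrained run is ≈ 0.04: the forced feature enters every fold's
selection with weight ≥ MinWeight, and the LP compensates by raising
the informative weights enough to dominate it on the training margins,
leaving a small residual error rate on test noise.

## Numerical choices

- Exact LP solve with HiGHS dual simplex (`scipy.optimize.linprog`,
  feasibility tolerances 1e-9): deterministic, certifiably optimal, no
  randomized presolve observable in results.  Solver failure raises;
  it is never reported as a silently suboptimal solution.
- Solution contracts: constraint residuals ≤ 1e-6, bounds within 1e-9,
  objective recomputable from the returned variables to 1e-8 relative.
- Selection ties (equal weights) break by input feature order;
  prediction ties break toward the earliest class in first-appearance
  order.
- Centroids are plain arithmetic means, reproducible to 1e-12 relative.

## Known limitations

- The rival-centroid constraint for `c > 2` ("beat every rival") is one
  of two defensible readings; the other ("beat the nearest rival") is
  weaker and was not implemented.
- The weighted-centroid predictor shares its metric with the training
  constraints; a forced high-weight noise feature therefore perturbs
  prediction more than it would a re-fit downstream classifier.
- No correlation structure in the generator, no probe-level noise
  model, and no column-generation for feature counts far beyond the
  microarray scale.
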