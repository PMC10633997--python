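# Methods

This note documents the models, the synthetic-data design, and the numerical
choices behind `moluq`. It is written for someone who wants to know what the
package actually computes and what a passing test suite does — and does not —
establish about real molecular data.

## The synthetic study system

Real descriptor datasets for properties such as aqueous solubility or redox
potential have three features that matter for evaluating uncertainty:
molecules form structural clusters; a low-dimensional learned embedding
carries correlated but not identical geometry; and measurement/label noise is
neither zero nor homogeneous. The generator reproduces these features with
known ground truth.

**Descriptors.** `n_molecules` points are drawn from `n_clusters` Gaussian
clusters (per-coordinate sd `cluster_spread`, default 1) in
`n_features = 32` dimensions. All cluster centers sit at distance
`30·cluster_spread` from the origin along a fixed random unit vector `u0`
(the "cone axis"), and are spread along a second orthogonal axis `v0` (the
"structural axis") over a total extent of `24·cluster_spread`, with gaps
growing geometrically (ratio 1.5). Two consequences are intentional:

- The top principal component of the z-scored descriptors aligns with `v0`,
  so PCA-percentile bins coincide with structural clusters — removing a bin
  removes a structural region, as required for the leave-bin-out metric.
- The geometric gaps make clusters differ in isolation: excising a
  well-isolated cluster hurts the model more and raises the distance-based
  uncertainty more, giving the Δerror–ΔUQ correlation a genuine signal to
  detect rather than five statistically identical scenarios.

**Embeddings.** A fixed seeded linear map of the descriptors to
`n_embedding = 8` dimensions plus 5% relative Gaussian noise (column scales
estimated once on a config-determined reference sample, so a training table
and an OOD pool share the identical map). This mimics the
descriptor-vs-embedding duality of fingerprint and learned representations:
correlated but distinct geometries.

**Targets.** `y = f(X) + ε` where the teacher `f` is a fixed seeded 2-layer
tanh network (16 hidden units, pre-activation gain 0.5, output rescaled to
unit sd on a reference sample). The gain keeps the teacher smooth enough
that a desk-scale network reaches near-noise-level error — necessary for any
noise-recovery experiment — while remaining nonlinear enough that tree and
network models retain nontrivial, structured errors.

**Noise.** `ε ~ N(0, σ(x)²)` with
`σ(x) = noise_base + noise_hetero · sigmoid(w_g·(x − x̄)/√p)`, defaults
0.1 and 0.6. The noise sd therefore varies smoothly between 0.1 and 0.7
against a unit-scale signal, a contrast strong enough that a mean-variance
head can be tested for *recovering* it. The heteroscedastic form is an
assumption of this package: nothing is known about the noise structure of
the real curated datasets, so recovery results here demonstrate correctness
of the machinery, not a claim about laboratory data.

**OOD pool.** Pool molecules start at a cluster center plus within-cluster
noise and are displaced along `−u0` by graded multiples (j/8, j = 0..32) of
`ood_displacement` (default 15·cluster_spread). Because the entire training
distribution occupies a cone around `+u0`, the maximum bounded cosine
similarity `(1 + cos)/2` of a pool molecule to the training set sweeps
continuously from ≈1 (multiple 0) to ≈0.05 (largest multiple, nearly
antipodal to everything). This is what makes downsampling to a uniform
similarity histogram over [0, 1] feasible — with isotropic cluster centers
the similarity would be bounded below by ≈0.5 and half the strata would be
empty. Pool targets come from the same teacher, so pool molecules can be
"labeled" during active learning.

**What the generator does not emulate.** Discrete fingerprint bit vectors
and their Tanimoto metric; heavy-tailed or censored label noise; activity
cliffs (the teacher is smooth); assay batch effects; any chemistry. Passing
tests show the estimators, metrics and experiment logic behave correctly on
a system with known truth — they do not certify performance on real
chemical space.

## Models

**Feedforward regressor.** A ReLU network on z-scored descriptors
(z-scoring statistics from the training partition only; the target is also
standardized internally and predictions are returned in original units).
Default 128/64 hidden units (64/32 in the desk-scale study profiles),
dropout 0.2, Adam (lr 1e-3, batch 128), early stopping on validation loss
with patience 20 and best-weight restore. The implementation is a compact
numpy engine with hand-derived gradients for all three heads, verified
against central finite differences in the test suite. All training is
deterministic given the spec seed.

Three heads:

- *point*: squared error.
- *mve*: outputs (μ, s); σ² = softplus(s) + 1e-6; Gaussian NLL loss. The
  first 50 epochs train the mean alone (warm-up) — joint training from a
  random start lets early variance estimates swallow mean error and
  destabilizes both.
- *evidential*: outputs mapped to (γ, υ, α, β) with υ, β = softplus + 1e-6
  and α = 1 + softplus + 1e-6 (guaranteeing finite NIG moments). Loss is
  the marginal Student-t NLL plus the evidence regularizer
  λ·|y−γ|·(2υ+α).

**Evidence regularizer weight.** λ defaults to 0.05 (configurable). At the
often-cited λ = 0.01 the learned evidence surface is nearly flat off the
training manifold at this data scale: under extrapolation both υ and β
collapse to their softplus floors and the epistemic variance β/(υ(α−1))
becomes a ratio of floors with no reliable direction. At λ = 0.05 the
evidence is pushed down wherever errors are high, and the epistemic
component grows monotonically with dissimilarity from the training data, as
the method intends. The reported evidential uncertainty defaults to the
epistemic component; aleatoric and total are available.

**Gradient boosting.** LightGBM. The mean model uses 500 trees, depth 6,
learning rate 0.05. Quantile (pinball) models use a deliberately more
regularized profile — 30 trees, 15 leaves, `min_child_samples` 100 —
because boosted quantile fits at n ≈ 4–5k overfit the conditional
quantiles and under-cover badly (≈60–70% for the P10–P90 interval, and
validation-based early stopping does not repair it, since the overfitting
is in the leaf values the pinball gradient drives to the sample extremes).
The regularized profile restores ≈78–80% held-out coverage, which is what
makes the half-interval uncertainty an error-scale quantity. Crossed
quantile pairs (upper below lower) are clipped to σ = 0 with a warning.

**Uncertainty unit convention.** Ensemble, MCDO, MVE and evidential all
report a standard deviation (not a variance), so σₜ enters the RMV of the
calibration metric on the error scale. Rank-based metrics are unaffected by
this choice (monotone transform), which the tests verify. Ensembles use the
population (divide-by-M) standard deviation; ensemble size defaults to 5
and MCDO to 30 passes with the training dropout rate.

## Metrics and scenario construction

- ENCE uses N = 10 equal-count bins (rank-based binning with stable
  tie-breaking, sizes within ±1), which avoids the empty-bin/zero-RMV
  pathologies of equal-width binning. A bin with RMV = 0 is an error;
  an uncalibrated estimate yields a flagged not-applicable result.
- ρ_error correlates per-sample absolute error with σₜ.
- ρ_ood is Spearman(σₜ, 1 − similarity): positive = dissimilar molecules get
  higher uncertainty, so "bigger is better" for every correlation column.
- ρ_Δerror: per scenario, ΔRMSE and Δ(mean σₜ) are both computed on the
  removed bin's *test* molecules, under the full model and the bin-removed
  model; the reported value is the Spearman correlation over scenario
  points. PCA is fit on the z-scored full dataset (the binning describes
  the data, not a particular split); train and validation are purged, test
  is untouched.
- Similarity-to-training scores use the maximum bounded cosine similarity
  against a seeded random training subset (default 1000). Uniform
  downsampling uses 10 equal-width strata with per-stratum quotas within
  ±1; an unfillable stratum is a hard error naming the deficient strata.
- Butina clustering is the classical sphere-exclusion procedure on a
  precomputed similarity matrix: repeatedly seed a cluster at the
  unassigned item with the most unassigned neighbors above the threshold
  (lowest index on ties), assign and remove. An exhaustive simulation of
  the same rule serves as the oracle in tests.

## Active learning

One iteration of pool-based selection, evaluated against a seed-paired
random baseline: per repetition both arms share the identical initial
training sample, and batch-selection randomness is keyed by
(seed, repetition, strategy) — so a random-vs-random comparison is exactly
zero, and paired one-sided t-tests are valid. Selection probability is
linear in σₜ (a molecule with twice the uncertainty is twice as likely per
draw), realized as sequential draw-and-renormalize without replacement;
zero-σ molecules have zero probability (no floor; if positive-weight
molecules run out the batch is completed uniformly with a warning).
Baselines: uniform random; diversity (weights ∝ mean pairwise distance in
embedding space, interpreted over the candidate pool); and an OOD-only
oracle that samples uniformly from the removed bin (capped at the bin pool
size with a warning). Evaluation reports RMSE on the removed-bin, remaining-
bins, and whole test subsets, percentage improvement over the random arm,
and the one-sided paired p-value (flagged degenerate when differences have
zero variance). The full grid is 4 initial fractions × 6 batch sizes = 24
combinations × 15 leave-bin-out scenarios = 360 experiments at 30
repetitions; the default runner profile is a reduced grid (1 fraction, 2
batch sizes, 3 scenarios, 5 repetitions) sized for a single-CPU desk run,
with per-cell JSON caching so interrupted runs resume.

## Problem sizes used by the reported numbers

`scripts/acceptance.py` runs: MVE recovery and interval coverage on
5000-molecule datasets (median over 3 data replicates); the true-σ
calibration check at n = 20000; ρ_ood on a 500-molecule uniform-similarity
pool; the Δerror sweep at n = 3000 with 1 component × 5 bins over 5 data
seeds (median); and the active-learning comparisons at n = 3000 with 10
repetitions. These sizes were chosen as the package's desk-scale study
conditions; quantities at this scale are stochastic, and replicate medians
are reported where a single draw would be noisy.

## Known limitations

- The numpy training loop is single-threaded and desk-scale; it is not a
  general-purpose deep-learning stack.
- Evidential OOD behavior depends on the regularizer weight; the default is
  documented above, and conclusions about evidential UQ should be read as
  conditional on it.
- The diversity baseline's reference set is interpreted as the candidate
  pool (the natural reading for pool-based selection).
- Δerror correlations over 5 scenario points are coarse (Spearman on 5
  ranks); the reduced runner profile exists for speed, not precision.
- The synthetic similarity is a bounded cosine on dense vectors, not a
  fingerprint Tanimoto; its distance ranges [0, 2] and its qualitative
  behavior match, but absolute similarity values are not comparable to
  fingerprint studies.
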