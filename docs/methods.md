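# Methods

## The selection problem

A docking campaign fixes one receptor and screens many ligands; each
(ligand, algorithm) pair is docked repeatedly because the Lamarckian
Genetic Algorithm (LGA) is stochastic. No single LGA parameterization wins
on every ligand — performance is complementary across instances — so a
per-instance selector that maps ligand features to the most suitable
configuration can outperform every standalone configuration. `dockselect`
implements that selector, the evaluation protocol that quantifies the
claim, and the post-hoc analyses of the algorithm and instance spaces.

## Data model

* **Portfolio** `A`: 28 LGA configurations — the 27 distinct combinations
  of population size {50, 150, 200}, mutation rate {0.02, 0.5, 0.8} and
  energy-window size {10, 30, 50} with the pseudo-Solis–Wets local
  searcher, plus one entry repeating the default parameters
  (150, 0.02, 10) with the classical Solis–Wets searcher.
* **Performance matrix** `P(A, I)`: complete m×n matrix of aggregated
  binding energies in kcal/mol (lower is better). Aggregation over the
  per-pair runs is `AVG` (mean), `BEST` (minimum — an extreme-value
  statistic, so AVG and BEST selectors can legitimately disagree) or
  `MEDIAN`. Missing cells are rejected at construction; sparse matrices
  are out of scope.
* **Rank matrix** `R`: row-wise ranks of `P`, rank 1 = lowest energy,
  average-rank ties. Average ties make every row sum exactly n(n+1)/2,
  which the tests exploit as an invariant. Ranks, not raw energies, are
  the selector's training signal: they are scale-free and robust to
  per-ligand energy offsets.

## The selector

1. **Factorization.** Truncated SVD of the *uncentered* rank matrix,
   `R ≈ U_k Σ_k V_k'` with default k = 5. No centering is applied: every
   rank row has the same mean (n+1)/2, which the leading singular
   component absorbs harmlessly. Instance latent factors are `X = U_k Σ_k`
   and algorithm factors `V = V_k` (orthonormal). Folding Σ into the
   instance side makes the regression targets carry the magnitude
   information and leaves rank prediction a plain inner product; the
   alternatives (regressing onto `U` or `U Σ^{1/2}`) differ only by a
   per-dimension rescaling of the targets.
2. **Regression.** A random-forest regressor (default 100 trees, the
   scikit-learn default; all other hyperparameters at library defaults)
   maps the instance feature vector to the k latent factors. One
   multi-output forest is the default; `per_output=True` fits k separate
   forests (seeds derived as seed + output index). All randomness flows
   from `SelectorConfig.seed`.
3. **Prediction and selection.** For features x, the predicted rank row is
   `f(x) V'`; the selected algorithm is its argmin. Exact score ties break
   by lower training mean rank, then portfolio order. Selection is
   invariant under any strictly increasing transform of the scores.

Models serialize to a single joblib archive (config, feature names,
algorithm ids, factors, fitted forest); loading reproduces predictions
bit-for-bit.

## Feature engineering

Descriptor tables pass through a fixed pipeline: drop features that are
exactly 0 for all instances, drop near-constant features, min–max
normalize to [0, 1]. "Near-constant" is operationalized as: the single
most frequent value covers ≥ 99 % of instances (`dominance=0.99`,
configurable) — a testable rule for a filter that is usually stated only
qualitatively. Constant columns under min–max map to 0 rather than
erroring, keeping pipelines composable when a filter was skipped.
Fingerprint tables are binary; the canonical substructure fingerprint is
881 bits. Feature subsets are chosen by Gini importance, either by a score
cutoff (0.15 is the conventional threshold used in the examples) or top-n
with name-order tie-breaks.

Inside cross-validation, normalization parameters are fitted on training
rows only and applied to test rows *without clipping* (leakage-free); a
`global` mode normalizes once on all rows for replicating whole-data
analyses.

## Evaluation protocol

Tenfold cross-validation: a seeded shuffle followed by a contiguous
partition into folds whose sizes differ by at most one. Per fold the
selector is fitted on the other nine folds and selects one algorithm per
held-out instance; the *achieved energy* is the chosen algorithm's true
aggregated energy. Each meta-method (selector, baselines) is then ranked,
per instance, jointly with the n standalone energies — n+1 entries with
average-rank ties, so the selector always ties the algorithm it chose
(picking the best of [−8, −6] yields ranks 1.5 / 1.5 / 3). Standalone
algorithms' reported ranks come from the selector's joint list, giving one
table in which all n algorithms and the selector share a rank scale. A
`joint=False` mode instead reports the chosen algorithm's rank among the n
standalone entries only.

Baselines: **SBS** (single best solver — the algorithm with the best
training-fold mean rank, applied to all test instances; a whole-data SBS
exists in `baseline_metrics` for replication), **VBS** (virtual best
solver — the per-instance argmin, the oracle lower bound) and **random**
(uniform pick, averaged over 1000 seeded draws). By construction VBS ≤
selector on achieved energy for every instance; on a complementary
benchmark the selector should sit strictly between VBS and SBS in mean
rank. The random-draw generator is seeded from (selector seed, fold seed),
making reports reproducible bit-for-bit.

## Landscape analyses

* **Gini importance**: mean impurity-decrease of the forest, aggregated
  across trees and the k outputs, normalized to sum 1.
* **Algorithm similarity**: agglomerative clustering (average linkage,
  Euclidean) on the algorithm latent factors *weighted by the singular
  values* (`V diag(s)`). The weighting matters in degenerate cases: when k
  exceeds the rank of the rank matrix, the orthonormal factors of
  zero-variance directions are arbitrary, and only the weighted rows make
  identical rank columns coincide (first merge at height 0). In
  non-degenerate cases it simply weights each latent axis by the rank
  variation it explains.
* **Portfolio reduction**: cut the dendrogram at the leaf–leaf merges
  (`lowest_pairs`: the mutually most-similar pairs) or one level above
  (`one_higher`), and keep per cluster the member with the lowest training
  mean rank (ties → portfolio order). The cluster-representative rule is a
  package choice; sub-portfolios reported in the literature are typically listed without
  one.
* **Instance space**: PCA (deterministic) and t-SNE (seeded; perplexity =
  min(30, (m−1)/3), recorded in the embedding metadata) to 2-D; k-means
  over k ∈ [2, 15] with the mean silhouette coefficient selecting k;
  per-cluster five-number summaries (Tukey 1.5·IQR whiskers) as the
  numeric backbone of box plots.

## Synthetic benchmark

The generator emulates the statistical structure the selector assumes,
with full ground truth and no docking:

* Instances are assigned round-robin to `n_clusters` latent clusters
  (think chemotypes). Every algorithm gets a base mean energy drawn
  uniformly from [−7, −5] kcal/mol, shared across clusters; within cluster
  c the planted winner (algorithm c) is forced `cluster_gap` kcal/mol
  below the best non-winner. Run energies are Gaussian around those means
  with SD `run_noise_sd`. Gaussian noise is the simplest model that makes
  AVG and BEST genuinely different statistics.
* With `cluster_gap = 0` the winner means are left untouched: the energy
  tensor then carries *no* cluster signal and the planted labels are
  uninformative — the null-control condition under which selection
  accuracy collapses toward 1/n_clusters.
* Descriptor-like features: `n_informative_features` noisy one-hot
  channels of cluster identity (0.8 vs 0.2 ± 0.05 jitter, clipped to
  [0, 1]) plus `n_noise_features` uniform channels. The informative
  channels are redundant (9 channels for 4 clusters by default) so both
  importance recovery and top-k selection have signal, and the noise
  channels make the importance-cutoff pathway exercisable.
* Fingerprint-like features: one random 881-bit template per cluster with
  independent 5 % per-bit flips.

Defaults are 300 instances × 12 algorithms × 50 runs, 4 clusters, gap 2.0
kcal/mol, run noise 0.5 kcal/mol, 9 + 110 descriptor channels — sized so
the full test suite runs in a couple of minutes on one CPU. A
`CAMPAIGN_SCALE` preset (1428 × 28 × 50) mirrors a real campaign's dimensions
for manual runs.

What the benchmark does **not** emulate: realistic descriptor marginals or
correlations, energy distributions of real force fields, heavy-tailed run
noise, or any chemistry. Passing tests demonstrate that the pipeline
recovers planted structure under its own assumptions; they say nothing
about how strongly real docking data exhibit that structure.

## Numerical and degenerate-input choices

* Rank ties: average ranks (preserves the row-sum invariant).
* SD everywhere is population SD (descriptive spread over a fixed
  instance set), not sample SD.
* `k = min(m, n)` reconstructs the rank matrix to machine tolerance; the
  factorization is deterministic up to sign flips, which cancel in every
  product the package exposes.
* Empty logs, missing grid cells, misaligned row ids, wrong-length
  feature vectors, unfitted models and out-of-range k all fail loudly
  with the offending names in the message.

## Problem sizes used by the test suite and acceptance script

Unit and property tests run on matrices up to 30×10 and benchmarks of
60–160 instances with 4–10 algorithms and 4–10 runs. The acceptance-level
recovery runs the default 300 × 12 × 50 benchmark with run noise 0.1,
tenfold CV, k = 5 and 100 trees; importance recovery uses five seeds of a
150 × 8 × 10 benchmark; silhouette recovery uses 120-point blob sets with
2 and 4 planted blobs over five seeds. These sizes are the package's
chosen desk-scale study conditions.

## Known limitations

* Rank tables from a real screening campaign cannot be reproduced
  without the original docking outputs; they require tens of millions of
  AutoDock energy evaluations. The synthetic benchmark is a structural
  stand-in with known truth, not a surrogate for them.
* Sparse performance matrices (instances not docked by every algorithm)
  are rejected rather than imputed, although factorization-based selectors
  can in principle handle them.
* Only SVD factorization and random-forest regression are provided; the
  module boundaries would admit alternatives, but none are implemented.
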