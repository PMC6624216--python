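# Methods

## Pipeline

One run executes five stages on a genes × cells matrix:

1. **Preprocess.** Counts/TPM are transformed to `log2(x + p)` with
   pseudocount `p = 1` (the only convention under which a zero count maps
   to zero log-expression). Genes are kept when both the mean and the
   sample standard deviation (divisor n−1) of their log2 values exceed 1;
   when more than 5000 genes qualify, the 5000 with the largest standard
   deviation are kept (ties by mean, then original order), and when fewer
   qualify they are all kept. Zero survivors raise an error rather than
   propagating an empty matrix. An optional minimum-detected-genes cell
   filter exists but is off by default — there is no published rule to
   mirror, so silence is the safer default.
2. **Split.** `round(rate × n)` anchor cells (half-up, minimum 2) are drawn
   uniformly without replacement, deterministically from the seed.
   Stratified sampling is deliberately absent: it would require the labels
   being sought.
3. **Featurize.** Every involved cell becomes its vector of similarities
   to the anchors: Spearman (fractional/average ranks, then Pearson on
   ranks), Pearson, cosine, or Euclidean; `identity` skips projection and
   reproduces the raw-space SCC baseline. Anchors-vs-anchors and
   rest-vs-anchors matrices are blocks of one all-vs-anchors matrix, so
   clustering and classification share one geometry. Query rows are
   processed in fixed-size chunks: memory scales with the anchor count,
   not the cohort size. Zero-variance (or zero-norm, for cosine) cells are
   a hard error naming the offending cells — dropping them silently would
   desynchronize label alignment. Features are used as-is, with no
   recentering or scaling, and Euclidean distance between feature rows is
   the within-space metric everywhere downstream (it is what k-means
   minimizes over).
4. **Cluster** the anchor rows with one of three interchangeable backends:
   - `kmeans` — Lloyd iterations, k-means++ seeding, best of 10 restarts
     by within-cluster sum of squares, tolerance 1e-6, max 300 iterations.
     The objective is asserted non-increasing across Lloyd steps; a
     cluster emptied during assignment is re-seeded from the point
     farthest from its centroid (which may bump the objective once).
   - `kmedoids` — PAM on the Euclidean distance matrix: greedy BUILD
     initialization, then best-improvement swaps until no swap lowers the
     summed distance to medoids.
   - `ap` — affinity propagation on similarity = −squared Euclidean
     distance, damping 0.9, preference = median similarity; the cluster
     count emerges from the data. Non-convergence returns a flagged
     result with a warning instead of raising.
   The cluster count `k` is a user input for kmeans/kmedoids; no model
   selection is attempted.
5. **Classify.** Remaining cells get the majority label of their
   `k_neighbors = 5` nearest anchors. Tie policies are chosen so that
   training order can never change a label: neighbors are sorted by
   (distance, anchor id); vote ties go to the tied class with the smallest
   summed distance over its voting neighbors, residual ties to the
   smallest class id.

## Evaluation statistics

- **Silhouette** `s_i = (b_i − a_i)/max{a_i, b_i}` from a caller-supplied
  dissimilarity matrix (the pipeline passes Euclidean distances — raw
  expression space for "before", feature space for "after"). Singleton
  clusters and the degenerate `a_i = b_i = 0` case score 0 (Rousseeuw's
  convention). A single overall cluster is an error, not a zero vector.
- **NMI** is computed from the contingency table as `2·I(A;B)/(H(A)+H(B))`
  with `0·log 0 = 0`; the log base cancels, natural log is used. A scheme
  with a single cluster has zero entropy; NMI is then defined as 0,
  matching the independent-partitions limit. The result is clipped to
  [0, 1] against floating-point drift.
- **Rand / adjusted Rand** use the standard pair-counting identities; two
  trivial schemes (where max-index equals expected index) return 1.
- **Fraction improved** is the share of cells whose silhouette is strictly
  larger after projection.
- **Cross-rate consistency** runs the pipeline at two subsampling rates
  with paired seeds (`base_seed + repeat`, 10 repeats by default) and
  reports the NMI between the two full-cohort labelings — computed over
  *all* cells, anchors included — plus the Pearson correlation of per-cell
  silhouette vectors: once per run with its own predicted labels, and,
  when truth is available, once with the true labels in the two feature
  spaces (the subsampling-stability statistic).

## Synthetic data generator

The generator emulates a filtered multi-cluster UMI count matrix; its
defaults are the fixed "easy regime" the test suite quantifies, and they
are deliberately not tunable per-test:

| parameter | default | meaning |
| --- | --- | --- |
| `n_genes` | 500 | genes after informative-gene filtering of a real dataset |
| `n_cells` | 1000 | 5 balanced clusters × 200 cells |
| `n_marker_genes_per_cluster` | 50 | disjoint marker blocks |
| `log_fold_change` | 2.0 | minimum marker elevation (log2) |
| `lfc_gradient` | 0.5 | cluster c elevated by `lfc·(1 + 0.5c)` — crisp and subtle types coexist |
| `marker_dose_spread` | 0.5 | per-cell marker dose ~ U(0.5, 1.5) — within-type state variation |
| `dispersion` | 0.1 | NB overdispersion (var = μ + 0.1 μ²), typical of UMI data |
| `dropout_rate` | 0.3 | mean excess-zero rate |
| `dropout_concentration` | 25 | per-cell dropout ~ Beta(25·0.3, 25·0.7) — variable capture efficiency |

Baseline gene means are log-normal (meanlog 1, sdlog 1, natural log);
marker baselines are floored at the median baseline because real cell-type
markers are reliably detected genes. Counts are gamma–Poisson (numerically
robust at small dispersion); dropout zeros are injected per cell.

Two generator features deserve emphasis because they exist for scientific
fidelity, not convenience. With perfectly exchangeable cells, per-cell
silhouette variation within a cluster is pure sampling noise, so silhouette
vectors from two independently subsampled feature spaces could not
correlate — unlike real data, where borderline cells are borderline in any
representation. The graded cluster separations, per-cell marker dose and
per-cell capture efficiency give cells genuine, stable quality and identity
differences, which is what makes subsampling-stability statistics
meaningful on synthetic data. What the generator does *not* emulate: batch
effects, library-size gradients beyond dropout heterogeneity, continuous
trajectories, correlated gene modules outside marker blocks. Passing tests
therefore demonstrate correctness of the machinery and the claimed
qualitative advantages (feature projection improves silhouette agreement,
accuracy and cross-run consistency at low subsampling rates), not
performance on any particular tissue.

## Problem sizes and determinism

The test suite and the reproduction script run entirely on synthetic data
at desk scale: 1000-cell cohorts, 10 paired repeats for the recovery and
consistency protocols, 100 randomized instances for silhouette bounds, and
exhaustive enumeration oracles on ≤ 8 points for the clustering objectives.
Every stochastic component consumes an explicit integer seed
(`numpy.random.default_rng`); repeat r of an evaluation uses
`base_seed + r`. Identical seeds give byte-identical label files.

## Known limitations

- PAM uses best-improvement swaps, which is exact on the suite's scales
  but O(k·n²) per pass; very large anchor sets would want FastPAM-style
  acceleration.
- Affinity propagation offers no preference tuning to hit a target
  cluster count.
- Correlation features are dense; cohorts are processed in chunks but the
  anchors-vs-anchors block must fit in memory.
- The feature method enum is closed (spearman, pearson, cosine, euclidean,
  identity); learned projections (autoencoders, PCA loadings) are out of
  scope, though the backend contract shows where they would plug in.
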