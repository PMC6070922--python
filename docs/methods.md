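# Methods

## Pipeline

Given K ≥ 2 omics matrices over a shared cohort (aligned to the sorted
intersection of sample ids; n ≥ 3 required, zero-variance features dropped
at load, missing values refused rather than imputed):

1. **Per-view similarity.** Pearson correlation between every pair of
   patients over all of the view's features. A constant sample vector has
   no defined correlation; such pairs are set to 0 with a warning rather
   than propagating NaN.
2. **Fisher z-map.** r = arctanh(S) after clipping S to [−1+ε, 1−ε] with
   ε = 1e−7. The clip exists because duplicate samples produce S = ±1
   exactly; 1e−7 keeps the clipped z (≈ 8.4) well above any realistic
   similarity while staying finite.
3. **Per-pair regression correction.** For target view k and pair (i, j),
   the response stacks the view-k similarities of i and then j to each
   other patient t (ascending t; 2(n−2) rows), and each predictor column
   holds the matching similarities in one other view, in input view order.
   Ordinary least squares with intercept; the corrected similarity is the
   fit evaluated at the pair's own cross-view similarities. The residual
   variance σ² = RSS/max(1, rows − coefficients) is reported as the pair's
   similarity bias but is not consumed downstream.
4. **Possibility and scaling.** p = logistic(μ r′) with gain μ (default 3),
   then a scaled exponential transform with shift t (default 1).
5. **Fusion.** W = Σ w_k PM′_k, w on the probability simplex.
6. **Spectral clustering.** Normalized Laplacian L = I − D^{−1/2} W D^{−1/2}
   with the diagonal kept in the degree; the m bottom eigenvectors,
   row-normalized to unit length, partitioned by k-means with 20 seeded
   restarts (best within-cluster sum of squares). Labels are canonicalized
   by decreasing cluster size, ties by smallest member index; statistical
   comparisons should nevertheless use permutation-invariant scores (ARI).
7. **Weight selection.** All lattice points {w_k = a_k·s, Σ w_k = 1} for
   step s (default 0.05; C(1/s + K − 1, K − 1) points, vertices and edge
   points included), each scored by the multi-group log-rank p-value of its
   clusters and the mean silhouette on the fused matrix; ranked by p, ties
   broken by silhouette then lexicographic w. The regression stage does not
   depend on w, so it is computed once and reused across the lattice.

## The scaled transform's direction

The literal mirrored form of the final transform, 1/(1 + e^{p−t}), is
*decreasing* in the possibility p, which would invert the ordering of an
affinity matrix fed to spectral clustering and contradicts the transform's
purpose of sharpening contrast between high- and low-possibility pairs.
The package's default mode `increasing` uses the order-preserving mirror
1/(1 + e^{t−p}); both agree at p = t (value 0.5). `as_printed` retains the
literal decreasing form for anyone wanting exact reproduction of the
original formulation. This choice is deliberate and surfaced in the
`RunConfig.scale_mode` field rather than hidden.

## Separate vs pooled regression

`separate` (default) fits one model per (view, pair) exactly as the
training-set definition prescribes. `pooled` stacks the per-view row blocks
over every target view and fits a single model per pair, with predictor
columns taken in canonical rotation relative to the target view — one
defensible reading of learning a unified model by concatenating the
similarities across omics layers, useful when cohorts are small. The
rotation means a pooled coefficient is tied to a *relative* view position,
not a fixed dataset; users are warned this is an interpretation.

## A consequence of the correction worth knowing

Because view k's corrected similarity is predicted *exclusively from the
other views*, information flows across views by design: if only one view
carries subtype signal, that signal migrates into the corrected matrices of
the other views, while the informative view's own corrected matrix — being
predicted from noise — loses it. Weight searches therefore rank weightings
of the *corrected* matrices, which need not coincide with the raw views'
informativeness. The test suite asserts this behavior explicitly (the grid
ranking tracks cluster recovery, not raw-view identity).

## Numerical choices

- **Rank deficiency.** Duplicated or collinear views are not an error: the
  batched normal equations are solved through the pseudo-inverse of the
  Gram matrix, giving the minimum-norm coefficient vector (identical to
  `lstsq` on the design), which spreads weight evenly across duplicate
  predictors and leaves predictions well-defined.
- **Vectorization.** All O(n²) pair regressions of one view are solved in a
  single batched pass over a (pairs × rows × coefficients) tensor; n = 215,
  K = 3 (the largest published cohort shape) takes seconds on one CPU.
- **Diagonals.** The diagonal is carried through every stage (correlation 1
  → clipped Fisher value → possibility 1 → scale transform at p→1);
  self-pairs never appear as regression targets or training rows. The
  affinity diagonal is kept inside the degree matrix of the Laplacian.
- **Silhouette distance.** The conversion d_ij = max_offdiag(W) − W_ij
  (clipped at 0, zero diagonal) preserves similarity ordering without
  assuming a scale. An all-constant similarity yields silhouette 0 by the
  a(i) = b(i) convention.
- **Degenerate inputs.** Isolated nodes (zero affinity row sum) are an
  error naming the sample; an all-tied feature gets Kruskal–Wallis H = 0,
  p = 1; a death at time 0 is accepted.
- **Determinism.** All randomness flows from the run seed (k-means
  restarts; the eigensolver is deterministic); reruns of the CLI pipeline
  are bit-identical, verified by manifest hashes.

## Synthetic data

The generator plants the structure the method assumes: each view draws
cluster centroids with sd `signal_strength` on a `signal_fraction` of its
features (defaults 3.0 and 0.5, i.e. mean shifts of three noise sd on half
the features — a strong but attainable planted partition), adds unit
Gaussian noise, and ties survival to the subtype via exponential event
times with per-cluster hazards (defaults 0.004/0.002/0.001 per day, a
4-fold range comparable to good- vs poor-prognosis subtype contrasts)
under independent exponential censoring (default rate 0.0008/day, ~25–30%
censored). Default cohort: n = 90, three equal clusters, K = 3 views of
200 features. Not emulated: real assay marginals (methylation-beta
bimodality, count overdispersion), feature–feature correlation, batch
effects — so passing tests demonstrate the pipeline's statistical
machinery, not robustness to real-data artifacts.

A second generator plants an exact linear cross-view law on Fisher-scale
similarity matrices (predictor views = block-structured latent + symmetric
perturbation, target = β₀ + Σβ·predictors + symmetric noise) for
parameter-recovery tests; with σ = 0 every pair regression recovers the
coefficients to machine precision.

## Problem sizes in the checks

The planted-recovery and weight-grid checks run at n = 90, K = 3 (231
lattice points); the zero-signal null averages 20 cohorts at n = 45; the
log-rank calibration uses 3 × 100 subjects and 500 replications — 100 per
group because the G-sample log-rank's chi-square reference is measurably
anti-conservative below ~50 subjects per group (true size ≈ 0.06 at 20 per
group, ≈ 0.052 at 100; confirmed independently against R's
`survival::survdiff`, which matches this implementation's statistic to
1e-12).

## Limitations

- The per-pair regressions treat the 2(n−2) training rows as independent,
  but similarities sharing a patient are correlated; σ² is therefore an
  optimistic bias estimate. The original formulation has the same property
  and never consumes σ² downstream.
- Weight selection optimizes the log-rank p over ~231 candidates without
  multiplicity correction; the selected p-value is an optimistic summary,
  as in any grid-searched model selection.
- The number of clusters is a user input; no eigengap or stability
  heuristic is provided.
- Inputs are assumed normalized and complete; no imputation, batch
  correction, or feature selection is performed.
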