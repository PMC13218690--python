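# Methods

## Model and procedure

`tespipe` stratifies cancer patients into tumor ecosystem subtypes (TES)
using only somatic mutation calls. The underlying model is that a tumor's
phenotype is driven by which functional neighborhoods of the
protein-interaction network are disrupted, not by which individual gene
carries the mutation. Network propagation encodes this: each patient's
binary mutation vector becomes the restart distribution of a random walk
with restart (RWR) on the interaction graph,

    p_{t+1} = (1 - r) W p_t + r p_0,

whose fixed point p_inf = r (I - (1 - r) W)^{-1} p_0 distributes each
sample's unit of mutation mass over the network in proportion to proximity
to the mutated genes. W is the column-normalized adjacency, so p_t remains
a probability distribution at every step; convergence is geometric with
rate (1 - r).

The propagated profile is summarized per sample as ssGSEA enrichment of a
catalog of ecosystem gene sets (immune cell populations, proliferation,
angiogenesis, and similar programs). Genes are ranked by propagated value;
the enrichment score is the integrated difference between the weighted
in-set rank ECDF (weights rank^alpha) and the uniform out-of-set ECDF.
Scores are normalized by the global range of the raw matrix (NES), which
preserves cross-sample comparability — a per-sample normalization would
distort the geometry that K-means clusters.

Subtyping proceeds in three steps: univariate Cox regression of survival
on each gene set's NES retains prognostically informative sets (Wald
p < 0.05); K-means over k = 2..10 with the mean silhouette width selecting
k; and a deterministic label orientation naming the cluster with the
largest restricted-mean survival TES 1. A gradient-boosted classifier
trained on NES then lets new samples be subtyped without re-clustering.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| restart probability r | 0.75 | — | standard for mutation-profile smoothing; keeps most mass near the seeds while borrowing neighborhood information |
| convergence tolerance | 1e-6 | L1 mass | stopping rule of the iterative solver; the L1 norm measures probability mass moved per step |
| STRING score threshold | > 700 (strict) | 0–1000 confidence | STRING's "high confidence" band; strict inequality |
| ssGSEA exponent alpha | 0.25 | — | the established single-sample default; exposed as config |
| Cox filter threshold | p < 0.05 | Wald p | conventional screening level; configurable |
| k range | 2..10 | clusters | exhaustive scan; k chosen by max mean silhouette |
| K-means restarts | n_init = 25 | — | stabilizes the silhouette argmax across seeds |
| XGBoost | lr 0.1, 100 trees, depth 3, colsample 0.8 | — | grid-search winners (grid reproducible behind `tune()`); other parameters at library defaults |
| CV | 10-fold, stratified | — | stratification keeps class balance in small cohorts; both mean-fold and pooled accuracy are reported since the two definitions differ |

## Numerical choices

- **Residual norm.** The RWR stopping rule uses the L1 norm, matching
  probability-mass movement; with r = 0.75 the iteration contracts at rate
  0.25 and converges in ~15–25 iterations at tol 1e-6.
- **Batch propagation.** All samples are iterated as one dense block;
  converged columns are frozen so the block iteration is exactly the
  per-sample iteration run in parallel (agreement within 1e-9 is a tested
  contract, and the iterative result is tested against the closed-form
  linear solve at 1e-6 L-infinity).
- **Seed normalization.** Uniform mass over the in-network mutated genes;
  samples whose mutated genes all fall outside the network are excluded
  and reported, never silently dropped.
- **ssGSEA ties.** Propagated values of unreachable genes are exactly 0,
  so ties are real; they are broken by gene-name lexicographic order for
  determinism.
- **Cox fitting.** Newton-Raphson on the Breslow partial likelihood with
  step-halving, |Δβ| < 1e-8, ≤ 50 iterations; Wald p-values. Breslow is
  the simplest consistent tie rule and has a clean prefix-sum
  implementation; the solver is validated against an independent reference
  fit on a tied fixture and against lifelines on tie-free data (where
  Breslow and Efron coincide).
- **Silhouette.** Euclidean distance; singleton clusters contribute s = 0.
  NES columns are z-scored before K-means by default (flag-controlled):
  without standardization, sets with wider NES ranges dominate the
  distance. Ties in the k-selection argmax break toward smaller k.
- **Label orientation.** Restricted-mean survival (horizon = largest
  observed time), with RMST rounded at 1e-12 before comparison; exact ties
  break by cluster size then original label index, so orientation is
  invariant to input label permutations.
- **Fold changes on propagated values.** log2((m1 + eps)/(m2 + eps)) with
  eps = (smallest positive profile value) × 1e-3, since propagated
  probabilities can be exactly 0. Genes with both group means 0 get
  log2FC = 0 and a degeneracy flag. Raw p-values are reported by default;
  Benjamini-Hochberg is available behind a flag.
- **Train/test split.** Training size floor(0.7 n) under a seeded shuffle
  (a 7:3 split of 2,526 samples gives exactly 1,768 / 758).
- **Feature attribution.** XGBoost's native TreeSHAP (`pred_contribs`),
  mean absolute value per feature; the trained model is stored as a raw
  Booster with a JSON feature manifest so saved models reload without
  scikit-learn wrapper state.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, at
desk scale (defaults: 300 samples × 300 genes, 68 gene sets, two
subtypes):

- **Network:** preferential attachment (Barabási–Albert, m = 3), because
  PPI degree distributions are heavy-tailed and RWR behavior depends on
  hubs; integer edge scores drawn from 701..1000 so every edge survives
  the strict > 700 threshold.
- **Drivers:** one connected module of 10 genes per subtype (BFS from a
  random root, disjoint across subtypes). Samples mutate their subtype's
  drivers with probability 0.8 and every gene with background probability
  0.02; all-zero samples are resampled (cap 100) rather than dropped so
  the cohort size is exact.
- **Gene sets:** each subtype's module is planted inside 8 of the 68 sets;
  the remainder are random draws of 10–30 genes. Planting makes the Cox
  filter and the clustering signal controllable.
- **Survival:** time ~ Exponential(h) with h = baseline ×
  HR^(subtype − 1) (baseline 0.01/month, HR 3 — for two subtypes this is
  a single multiplicative contrast on subtype 2), censored by an
  independent Exponential(0.005) follow-up; event = 1 iff death precedes
  censoring. Exponential survival matches the proportional-hazards
  assumption of the Cox filter and gives closed-form oracles (group-wise
  hazard MLE = events / time at risk).

The mutation sparsity (background rate, drivers per subtype, planted-set
count) is config-exposed rather than hard-coded, since real cohort
sparsity varies by panel and tumor type.

What the generator does **not** emulate: mutational-signature structure
(trinucleotide context), copy-number and structural variants, gene-length
and coverage biases, clinical covariates beyond survival, and the
version-dependent size of real interaction databases. Passing tests
therefore demonstrate correctness of the algorithms and recoverability of
planted structure under proportional hazards — not clinical performance on
real cohorts.

## Problem sizes

Tests and the acceptance script run the full pipeline on 300-sample,
300-gene cohorts (20 replicates), calibration checks at 500 null
replicates, and brute-force oracles at n ≤ 8 (ssGSEA set enumeration) or
n ≤ 50 (silhouette). These sizes give stable statistics while keeping the
whole suite under a minute of compute for the unit layer and a few tens of
seconds for the end-to-end layer.

## Known limitations

- The Cox filter is univariate and applied before clustering; gene sets
  with small but real effects can be screened out, and the filter's
  p-threshold is a convention, not an optimized choice.
- K-means with Euclidean distance assumes roughly isotropic clusters in
  z-scored NES space; elongated or nested ecosystem structure would favor
  other clusterers.
- The classifier's binary-logistic default targets the two-subtype case;
  multiclass labels are handled by the library's softmax generalization
  but are not the tuned path.
- Propagation treats the network as static and unweighted by default
  (confidence-weighted transition is available behind a flag); edge
  direction and sign are out of scope.
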