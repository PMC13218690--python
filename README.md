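# tespipe

Tumor ecosystem subtyping (TES) from somatic mutation profiles.

Somatic mutation calls from targeted panels are sparse and binary, which
makes them awkward inputs for clustering and survival modeling: two
patients whose tumors disrupt the same pathway through different genes look
entirely dissimilar. `tespipe` addresses this by smoothing each patient's
binary mutation vector over a protein–protein interaction network with a
random walk with restart (RWR), summarizing the smoothed profile as
single-sample gene-set enrichment scores (ssGSEA) over tumor-ecosystem gene
sets, and clustering patients into prognostic subtypes. It is aimed at
cancer genomics researchers who want a tested, reusable implementation of
this network-propagation subtyping workflow, plus a synthetic-cohort
generator for validating it without access to restricted clinical data.

## Method

1. **Propagation.** For a patient with mutated gene set *M*, the seed
   distribution p₀ places mass 1/|M| on each in-network mutated gene, and
   the walk iterates

   p<sub>t+1</sub> = (1 − r) W p<sub>t</sub> + r p₀

   with restart probability r = 0.75 and column-stochastic transition
   matrix W (normalized adjacency of the interaction network, edges with
   STRING combined score > 700), stopping when ‖p<sub>t+1</sub> −
   p<sub>t</sub>‖₁ < 10⁻⁶. The steady state p<sub>∞</sub> is a continuous
   mutation profile that conserves probability mass.

2. **Scoring.** ssGSEA with exponent α = 0.25 converts each propagated
   profile to an enrichment score per ecosystem gene set (integrated
   difference between the weighted in-set and uniform out-of-set rank
   ECDFs); scores are normalized to NES by the global range of the matrix.

3. **Subtyping.** Gene sets are filtered by univariate Cox regression
   against overall survival (Wald p < 0.05; Breslow ties), patients are
   clustered by K-means on the retained NES columns for k = 2..10, k is
   chosen by the maximum average silhouette width, and labels are oriented
   so TES 1 is the better-prognosis cluster (largest restricted-mean
   survival).

4. **Characterization & prediction.** Between-subtype Wilcoxon rank-sum
   comparisons of NES, differential propagated genes (|log₂FC| > 1 and
   p < 0.05), and an XGBoost classifier (learning_rate 0.1, 100 trees,
   depth 3, colsample_bytree 0.8, binary logistic, 10-fold stratified CV)
   with mean-|SHAP| feature ranking, so new samples can be subtyped from
   their NES alone.

## Worked example

```python
from tespipe.synthetic_data import SyntheticConfig, generate_cohort
from tespipe.propagation import propagate_cohort
from tespipe.geneset_scoring import score_profile
from tespipe.subtyping import filter_prognostic_genesets, fit_subtypes
from tespipe.survival import logrank_test

cohort = generate_cohort(SyntheticConfig(seed=1))   # 300 samples, 300 genes
profile = propagate_cohort(cohort.mutation_matrix, cohort.network)
nes, _ = score_profile(profile.values, cohort.genesets)
kept, _ = filter_prognostic_genesets(nes.scores, cohort.survival)
result = fit_subtypes(nes.scores, cohort.survival, kept_genesets=kept, seed=1)
stat, p = logrank_test(cohort.survival, result.labels)
```

Output:

```
prognostic gene sets kept: 59 / 68
selected k = 2
silhouette by k: {2: 0.422, 3: 0.232, 4: 0.068, 5: 0.052, ...}
log-rank between TESs: chi2 = 66.1, p = 4.35e-16
ARI vs planted labels: 1.000
```

Of the 68 synthetic ecosystem gene sets, 59 are significantly associated
with survival and survive the Cox filter; the silhouette trace peaks
sharply at k = 2, recovering the two planted subtypes exactly (adjusted
Rand index 1.0), and the two TESs have clearly separated survival curves.

The same workflow is available from the shell:

```bash
tes simulate --seed 1 --outdir cohort/
tes propagate --matrix cohort/mutations.tsv --network cohort/network_links.tsv --out prop.tsv
tes score --profile prop.tsv --gmt cohort/genesets.gmt --out nes.tsv
tes subtype --nes nes.tsv --survival cohort/survival.tsv --seed 1 --out labels.tsv
```

or end to end via `tes run --config pipeline.yaml --outdir out/`, which
also writes NES comparisons, differential genes, a trained classifier and
a reproducibility manifest.

## Layout

- `tespipe.synthetic_data` — scale-free networks, planted driver modules,
  gene sets, exponential survival with per-subtype hazards
- `tespipe.mutation_io` — MAF-like tables → mutation-count matrix
- `tespipe.ppi_network` — STRING links → column-stochastic transition matrix
- `tespipe.propagation` — per-sample and batch RWR
- `tespipe.geneset_scoring` — ssGSEA and NES normalization, GMT I/O
- `tespipe.survival` — Kaplan-Meier, log-rank, univariate/multivariate Cox
- `tespipe.subtyping` — Cox filter, silhouette-selected K-means, label orientation
- `tespipe.characterization` — Wilcoxon comparisons, differential genes
- `tespipe.classifier` — XGBoost training, CV evaluation, SHAP ranking
- `tespipe.pipeline` / `tespipe.cli` — orchestration and the `tes` command

See `docs/methods.md` for modeling assumptions, parameter choices and
limitations.
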