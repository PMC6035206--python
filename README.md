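# ovimmune

Comparative transcriptomic immune profiling of ovarian tumours, built for
the setting where a small cohort of formalin-fixed (FFPE) case tumours —
for example ovarian tumours from patients with anti-Yo paraneoplastic
cerebellar degeneration — is compared against large fresh-frozen (FF)
public control cohorts. The package turns that analysis into a tested,
reusable pipeline that runs end to end on synthetic data with known
ground truth, so every stage's statistical behaviour (calibration,
recovery, determinism) can be verified before it touches real data.

## What it computes

Given log2 gene × sample expression matrices with cohort / preservation /
phenotype metadata, plus gene annotation (BED), gene sets (GMT) and
survival tables (CSV):

- **harmonize** — merge cohorts on their common gene set, remove genes
  known to differ between FFPE and FF preparations (they are confounded
  with phenotype when all cases are FFPE), quantile-normalize, and report
  the percentage of a DE ranking that overlaps the artefact list.
- **diffexpr** — per-gene two-group linear model with empirical-Bayes
  variance moderation: the moderated variance is
  s̃² = (d₀s₀² + d·s²)/(d₀ + d), with the prior (d₀, s₀²) estimated by
  method of moments from the log sample variances; t reference with
  d₀ + d df; Benjamini–Hochberg FDR; DE selection at |log₂FC| > 1.1 and
  p < 0.001 (strict).
- **gsea** — single-sample GSEA (rank-weighted, weight exponent w = 0.75
  by default), exact upper-tail hypergeometric enrichment, and
  brain-structure enrichment of the DE signature: per-structure score
  Σ|log₂FC| over DE genes in the structure, with max-statistic
  permutation control of the FWER at 0.05.
- **deconv** — cell-type fractions by non-negative least squares against
  a signature matrix (linear scale), sum-to-one normalized, with a
  gene-permutation p-value per sample (samples kept at p < 0.1);
  per-cell-type rank-sum group comparisons; ssGSEA immune/stromal scores.
- **genomic** — median nearest-neighbour distance of a gene list, its
  permutation null over random same-size gene sets (exhaustive when
  feasible), rainfall series, and sliding-window hotspot detection by
  observed/expected density ratio.
- **subtype** — ssGSEA subtype scores (z-scaled), majority-vote consensus
  across scorers, PCA of score matrices, and a leave-one-out
  nearest-centroid phenotype classification with Clopper–Pearson CI.
- **survmeta** — per-cohort Cox proportional-hazards fits of a gene's
  expression (Newton–Raphson, Breslow ties, optionally adjusted for
  debulking surgery and FIGO stage), pooled by inverse-variance
  fixed-effect meta-analysis: β̂ = Σwᵢβᵢ/Σwᵢ with wᵢ = 1/seᵢ².
- **synthdata** — generates all of the above inputs with planted DE
  genes, FFPE artefact genes, a planted genomic cluster, known mixture
  fractions, a known log hazard ratio, and an enriched structure, and
  records the ground truth.

## Worked example

```python
from ovimmune import (SimulationConfig, simulate_all, merge_cohorts,
                      remove_preservation_genes, quantile_normalize,
                      fit_linear_de, select_de, clustering_test,
                      detect_hotspot, meta_analyse_gene)

study = simulate_all(SimulationConfig(seed=1))   # 12 FFPE cases, 200 FF controls
merged = merge_cohorts(study.cohorts)
merged, removed = remove_preservation_genes(merged, study.truth.ffpe_genes)
merged = quantile_normalize(merged)

table = fit_linear_de(merged)
de = select_de(table)                            # |log2FC| > 1.1 and p < 0.001
print(len(de), removed)                          # 83 150

ct = clustering_test(de, study.annotation, n_perm=1000, seed=1)
hs = detect_hotspot(de, study.annotation)
print(round(ct.p, 4), hs.chrom, hs.nearest_gene) # 0.011 chr3 g1850

meta, fits, forest = meta_analyse_gene(
    study.survival, covariates=("expression", "debulking", "stage"))
print(round(meta.hr, 3), [round(c, 3) for c in meta.ci])  # 1.131 [1.072, 1.194]
```

83 of the 2000 simulated genes pass the DE thresholds (the generator
planted 100, some of which fall below the fold-change cutoff at this
noise level); the 150 FFPE artefact genes were removed before testing.
The DE list shows significant genomic clustering (permutation p ≈ 0.011)
and the detected hotspot window sits on the planted cluster, naming a
gene at the planted locus. The pooled fixed-effect hazard ratio for the
simulated expression effect at 10 studies × 200 patients is 1.131
(95% CI 1.072–1.194) against a planted 1.07; at 10 × 2000 patients (the
acceptance script's setting) the estimate tightens to 1.049 (1.032–1.067).

The same run is available from the shell:

```sh
ovimmune run-all --outdir run1 --seed 1
ovimmune report --outdir run1
```

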