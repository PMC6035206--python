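# Methods

## Setting and model

The pipeline addresses a case–control design that is common in rare-disease
tumour transcriptomics: a handful of archival FFPE case tumours compared
against hundreds of fresh-frozen controls pooled from public cohorts. Three
statistical hazards dominate that design and drive the architecture:

1. **Preservation confounding.** Every case is FFPE and every control is
   FF, so any gene affected by fixation is perfectly confounded with
   phenotype. The pipeline removes a user-supplied list of FFPE-affected
   genes *before* differential testing, then reports the overlap between
   the top of the DE ranking and that list as a residual-confounding
   diagnostic (`preservation_overlap_fraction`).
2. **Tiny case group.** With ~12 cases, per-gene variance estimates are
   unstable; differential expression uses empirical-Bayes moderation.
3. **Multiplicity across heterogeneous analyses.** Each downstream module
   carries its own error control: BH FDR for per-gene tests, exact
   hypergeometric p for set overlap, max-statistic permutation FWER for
   structure enrichment, add-one empirical p for the genomic clustering
   test and the deconvolution fit.

## Differential expression

Per gene, logFC = mean(case) − mean(control) on the log2 scale, with the
pooled two-group variance s² on d = n₁+n₂−2 degrees of freedom. The
moderated variance is s̃² = (d₀s₀² + d·s²)/(d₀+d); the prior (d₀, s₀²) is
estimated by the method of moments from the distribution of log sample
variances (Fisher's z for variances: match mean and variance of
e = log s² − ψ(d/2) + log(d/2); d₀ solves ψ′(d₀/2) = Var(e) − ψ′(d/2) by
Newton inversion of the trigamma). When the observed spread of log
variances does not exceed the chi-square sampling spread, d₀ = ∞ and all
genes share s₀². The moderated t uses d₀+d df. Zero-variance genes are
assigned the smallest positive observed s² (with a warning) rather than an
infinite statistic. DE selection applies strict inequalities,
|log₂FC| > 1.1 and raw p < 0.001; both thresholds and the choice of raw
vs BH-adjusted p are parameters. Cohort membership is *not* adjusted for
by default (the cohorts are merged after FFPE-gene removal and quantile
normalization); a cohort fixed-effect model is available behind a flag.

## Quantile normalization

Standard cross-cohort microarray practice: each sample's sorted values are
replaced by the across-sample mean of sorted values; ties receive the mean
of the quantile values their ranks span (implemented as linear
interpolation of average ranks into the mean quantile vector). The
operation is idempotent and rank-preserving within samples.

## ssGSEA

Genes are ordered by decreasing expression. The score is
ES = Σᵢ (P_in(i) − P_out(i)), where P_in is the cumulative in-set
distribution weighted by rank^w (rank N for the top gene) and P_out the
unweighted out-of-set cumulative distribution. Weights are built from
ranks, not raw values, so the score is invariant under any strictly
monotone transform of the profile — the property that makes it safe across
platforms. w defaults to 0.75, the common convention. A set that covers
the whole profile (no out-of-set genes) or none of it is rejected. Scores
are not normalized across sets by default; subtype scoring z-scales within
each set across samples instead.

## Structure enrichment

The observed score of a structure is Σ|log₂FC| over DE genes in its gene
set (absolute weights: a structure enriched for strongly *down*-regulated
genes is as interesting as one enriched for up-regulated genes; a signed
variant would cancel them). The null draws random gene sets of the DE
set's size from the tested universe and records, per draw, the maximum
score across all structures; comparing each structure against that
max-statistic null controls the FWER in the limit. Adjusted p-values use
the add-one rule, so they lie in [1/(1+B), 1] and are never zero.

## Deconvolution

Bulk profiles are modelled on the linear scale (log2 input is unlogged) as
non-negative combinations of signature columns; weights come from
non-negative least squares on the shared marker genes and are normalized
to sum to one. NNLS with sum-to-one normalization is used instead of the
ν-SVR solver popularised for this problem: it is deterministic,
closed-form reproducible, and equivalent on well-conditioned signatures
(the test suite verifies exact recovery on noiseless mixtures and
agreement with a brute-force constrained grid on two-type problems).
Per-sample significance permutes the mixture across genes and counts how
often the permuted reconstruction correlation reaches the observed one
(add-one rule); samples with p ≥ 0.1 are dropped before group comparison.
Group differences per cell type use the two-sided rank-sum test, exact
when both groups have ≤ 10 samples, normal approximation with tie
correction otherwise; a Fisher presence/absence mode (fraction > threshold)
is provided because the fraction contrast is sometimes reported that way.

## Genomic clustering and hotspot

The clustering statistic is the median over set genes of the distance to
the nearest same-chromosome set gene, start-to-start and strand-agnostic
(gene-to-gene distance has no canonical definition; start positions are
simple and translation-invariant). Genes alone on their chromosome are
excluded rather than scored infinite, keeping the median finite. The null
redraws same-size gene sets from the annotation; when C(N, k) ≤ 10,000 the
full combinatorial distribution is enumerated instead of sampled. The
one-sided empirical p uses the add-one rule; "clustered" means p < 0.05.
Hotspot detection slides half-overlapping windows (default 1 Mb), scores
observed/expected set-gene counts (expected proportional to the share of
annotation genes in the window), requires ≥ 3 set genes (no single-gene
hotspots), and names the annotation gene nearest the winning window's
midpoint. Because the synthetic generator places clustered genes uniformly
within the planted window, the anchor is exchangeable with its clustered
neighbours; recovery is therefore assessed as "the detected window
overlaps the planted window and the named gene lies inside it", which is
the identifiable version of naming the anchor.

## Subtype scoring and consensus

Subtype gene sets are scored by ssGSEA and z-scaled within subtype across
samples. Multiple scorers (e.g. different subtype set collections) each
vote their argmax; the majority wins and ties break toward the subtype
with the highest mean z across scorers. The leave-one-out phenotype check
z-scales genes with training-fold statistics only and assigns the nearest
phenotype centroid; accuracy comes with the exact two-sided 95%
Clopper–Pearson interval. PCA of score matrices is a centred SVD.

## Survival meta-analysis

Each cohort is fitted by maximizing the Cox partial likelihood with
Newton–Raphson and step-halving; ties are handled by Breslow's
approximation (Efron behind a flag — simulated exponential times make ties
rare). Covariates are the gene's expression per unit (per-SD scaling
available), an indicator for suboptimal debulking, and two indicators for
FIGO stage II and III/IV against stage I. Convergence requires score norm
< 1e-8, relaxed to a relative log-likelihood criterion for large cohorts
where the score's floating-point rounding floor sits above the absolute
tolerance; standard errors come from the inverse observed information. A
monotone likelihood (perfect separation) is flagged as non-convergence —
detected by iteration exhaustion, a singular information matrix, or a
coefficient beyond ±10 per centred covariate unit. Study coefficients are
pooled with inverse-variance fixed-effect weights (no random-effects
model); forest tables report per-study HR, CI and percent weight plus a
flagged pooled row.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical *structure* the analysis assumes,
at sizes small enough for routine runs:

- **Cohorts**: 12 FFPE cases vs five FF control cohorts (40 samples each
  by default; exact per-cohort sizes, e.g. totalling 733 controls, can be
  given explicitly). 2000 genes with Uniform(5,10) log2 baselines; 100
  planted DE genes with logFC of random sign and magnitude N(1.5, 0.3²) —
  centred on the effect sizes the selection thresholds are meant to catch;
  150 FFPE-artefact genes shifted +1.0 in FFPE samples only; i.i.d.
  Gaussian noise, sd 0.3 on the log2 scale. Noise is additive Gaussian on
  log2 (the simplest model that approximately preserves linear mixing);
  the variance structure of real arrays is not estimated — noise sd is a
  free parameter, not an estimate.
- **Mixtures**: seven cell types — six immune types with distinct planted
  case/control mean fractions (CD8 T 25.8 vs 4.1%, Tregs 16.32 vs 1.8%,
  M2 macrophages 0.78 vs 18.99%, naive B 6.31 vs 0.3%, monocytes 11.68 vs
  1.86%, resting memory CD4 0.03 vs 8.07%) plus a remainder compartment so
  fractions sum to one. Per-sample fractions are Dirichlet around the
  group means (concentration 150 ≈ 3-point sd for a 20% component). The
  signature is block-structured (own markers ~100, background ~1, linear
  scale) and hence well-conditioned — real signatures are far more
  collinear, so recovery results here bound the method's best case, not
  its field performance.
- **Genome**: genes uniform per chromosome (5 × 100 Mb) except 30% of DE
  genes placed in one 1 Mb window around an anchor DE gene.
- **Survival**: 10 studies × 200 patients; expression standard normal;
  exponential event times with hazard h₀·exp(β·x + 0.5·suboptimal +
  0.3·stageII + 0.6·stageIII/IV), h₀ = 0.01/month, planted β = log(1.07);
  independent exponential censoring tuned to a 30% rate.
- **Structures**: 20 structures of 50 genes; one contains half the planted
  DE genes (the "cerebellum-like" structure), the rest are random draws.

One root seed drives everything; each generator derives an independent
substream via fixed spawn keys, so adding a generator never perturbs the
others and identical seeds give bit-identical outputs.

Deliberately **not** modelled: probe-level intensities and RNA
degradation, platform-specific probe↔gene mapping, correlated gene–gene
noise, collinear signatures, covariate-dependent censoring, batch
location/scale effects beyond the constant FFPE shift. Passing recovery
tests on this generator demonstrates correctness of the machinery under
its stated assumptions, not performance on real arrays.

## Numerical choices and degenerate inputs

- Empirical p-values everywhere use the add-one rule and can never be 0.
- Strict inequalities at all selection thresholds.
- BH FDR is delegated to statsmodels and cross-checked in tests against
  the literal step-up definition.
- Exact rank-sum enumeration only for groups ≤ 10 (cost), with an explicit
  p = 1 short-circuit for identical groups.
- Quantile normalization requires ≥ 2 samples; merging requires ≥ 2
  cohorts and disjoint sample ids; removing all genes is an error.
- Hotspot detection returns "no hotspot" (None) rather than raising when
  no window reaches 3 set genes.
- Problem sizes in the test and acceptance runs (2000 genes, 212–745
  samples, 1000 permutations, 10×2000 survival patients) were chosen as
  the smallest sizes at which the planted effects are comfortably
  identifiable under the generator's noise model.

## Known limitations

- Gene identifiers match by exact string only; no symbol aliasing.
- No ComBat-style batch adjustment; quantile normalization plus FFPE-gene
  removal is the whole harmonization story.
- The subtype consensus replaces externally trained classifiers with
  user-supplied gene-set scorers; the voting logic, not the published
  classifiers, is what is implemented and tested.
- Fixed-effect pooling only; between-study heterogeneity is not modelled.
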