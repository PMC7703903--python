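# Methods

`grexmeta` implements a two-armed transcriptome-wide association workflow
for discovering modifier genes of a quantitative disease phenotype, together
with a synthetic-cohort generator that instantiates exactly the generative
assumptions the workflow relies on. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## The model

Expression of gene *g* in tissue *t* is assumed linear and additive in the
dosages of cis variants:

    E_gt = sum_j beta_jgt x_j + e_gt,

with the genetically regulated component (GReX) T_g = sum_j w_j x_j
estimated by an elastic-net fit of expression on cis dosages. The phenotype
(knorma, a standardized lung-function score; higher = milder disease)
receives genetic signal only through the genetic expression component of a
small set of modifier genes:

    knorma = sum_g lambda_g G_g + covariate effects + noise,

so a variant affects the phenotype only insofar as it regulates expression.
A positive lambda (and hence a positive association coefficient of imputed
expression on knorma) is labelled "protective": more expression, milder
disease.

Two association arms test each (gene, tissue):

* **individual-level**: imputed GReX is regressed on knorma with sex and
  four genotype PCs as covariates, by Huber IRLS robust regression. The
  published analysis puts GReX on the left-hand side; we follow it, and note
  that with covariates this is not numerically identical to the conventional
  phenotype-on-GReX direction (a configuration switch offers the latter).
  Samples used in a tissue's model training are excluded first.
* **summary-level** (FUSION-style): z_twas = w'Z / sqrt(w'Rw), combining the
  marginal GWAS z-scores of the model variants through the weights with an
  LD correlation matrix R from a reference panel (here: the cohort's own
  genotypes), ridge-regularized as (1-λ)R + λI with λ = 0.1.

Per-tissue tests are combined per gene, per arm, by two methods each:

* **harmonic mean p** (both arms): raw HMP = (Σw)/(Σ w_i/p_i); the
  asymptotically exact adjusted p refers 1/HMP to the Landau distribution
  with location ln(k) + 0.874368 and scale π/2 (`scipy.stats.landau`).
* **empirical Brown's method** (individual arm): Fisher's X = −2Σ ln p
  calibrated to c·χ²_f with c, f from empirically estimated covariances of
  the −2 ln p transform of per-tissue statistics across genes (ECDF of
  |stat|, pairwise-complete genes, minimum 30 per pair, diagonal fixed at
  the theoretical 4). With zero covariance this is exactly Fisher.
* **omnibus test** (summary arm): χ² of the per-tissue z vector whitened by
  the correlation of predicted expression across tissues
  (C_ij = w_i'Rw_j normalized), dropping eigenvalues below 1% of the
  largest.

A gene is a platform candidate when both of that platform's combined
p-values are < 0.01, and a **consensus modifier** when all four are. Fixed
thresholds mirror the published analysis; BH q-values are reported
alongside. Pre-ranked GSEA ranks genes by −log10 of the maximum of a
platform's two combined p-values (ties broken lexicographically) and uses
the weighted Kolmogorov–Smirnov running sum (exponent 1 by default) with a
gene-label permutation null, one-sided by ES sign, NES = ES / mean same-sign
null |ES|, BH across sets.

## The synthetic cohort

`simcohort` draws, per gene, one LD block of hard-call genotypes from a
Gaussian copula: two latent haplotypes per sample follow an AR(1) process
with lag-one correlation `ld_rho`, thresholded at the normal quantile of a
uniform MAF in `maf_range`. Thresholding attenuates correlation — the
dosage-scale ceiling is (2/π)·arcsin(ld_rho) ≈ 0.71 at ld_rho = 0.9 — so
`ld_rho` is a latent, not a dosage-scale, correlation. Genes sit 10 Mb
apart (22 per synthetic chromosome) so 1 Mb cis windows never overlap.

Each gene gets `causal_variants_per_gene` causal cis variants with shared
base effects; each (variant, tissue) pair is active with probability
`tissue_sharing`, giving shared and tissue-specific eQTLs. In active tissues
the genetic component is rescaled so realized cis heritability equals
`cis_h2` in-sample; residual noise is independent across tissues. The
phenotype adds a 0.05 SD sex effect and 0.02 SD loadings on four synthetic
N(0,1) PCs — enough to exercise the covariate interface without modeling
population structure — plus standard-normal noise, and is re-standardized.
Marginal GWAS summary statistics are computed on the same cohort by
residualizing phenotype and dosages on the covariates.

Defaults: n_samples 2,000 (5,000 in the power experiments), n_genes 300,
variants_per_gene 30, ld_rho 0.7, maf 0.05–0.5, 3 tissues, 2 causal
variants per gene, cis_h2 0.3, tissue_sharing 0.8, 10 modifier genes at 1%
phenotypic variance each, 500 training samples per tissue. These sizes keep
every experiment minutes-scale on one CPU while leaving each stage's signal
comfortably detectable. All randomness flows from one integer seed; every
operation is a pure function of (config, seed) and re-runs are
bit-identical.

What the generator does **not** emulate: realistic human MAF spectra and
recombination maps, imputation dosage uncertainty, relatedness, population
stratification (the PCs carry no genotype structure), X-chromosome
inheritance, trans effects, and non-linear or interaction effects. Passing
tests therefore demonstrate internal correctness and calibration of the
machinery under the stated linear-additive model, not robustness to the
confounders of real cohorts.

## Model training

Per gene and tissue, expression is rank-inverse-normal transformed and
regressed on standardized cis dosages with an elastic net (mixing 0.5, the
PredictDB/GTEx convention), over a 100-point log-spaced penalty path from
the data-derived maximum down by 1e-3, with 10-fold seeded CV. Performance
is the squared Pearson correlation of pooled out-of-fold predictions with
observed expression plus the correlation-test p; weights come from a
full-data refit at the selected penalty, reported on the raw dosage scale.
Two numerical guards matter:

* out-of-fold predictions omit the complement-fold mean (expression is
  centered globally); including it leaks the classic CV fold-mean
  anti-correlation into the null R²;
* the CV-MSE-minimizing penalty is accepted only when it beats the
  intercept-only model by one standard error (a glmnet-style 1-SE rule
  applied to the null comparison); otherwise the gene is declared
  unpredictable. Without this guard, selection noise over the path makes
  the pooled out-of-fold R² anti-conservative: roughly a quarter of
  pure-noise genes would pass the imputable filter (R² > 0.01 and
  p < 0.05), versus essentially none with it, while recovery and cv R² on
  true single-eQTL genes are unchanged.

Degenerate inputs (constant expression, fewer than two usable cis variants,
zero-variance predictions) yield an empty model with cv R² = 0, p = 1.
Expression-covariate adjustment (PEER-style factors) is not applied by
default; the transform-only preprocessing is configurable.

## Harmonization and imputation

Model weights apply to the dosage of the model's effect allele. Matching is
by variant id, falling back to chrom:pos plus allele set. An allele swap
(model effect allele = cohort ref) contributes w·(2 − x): sign flip plus a
constant 2w, which makes GReX exactly invariant to cohort ref/alt
relabelling. Strand-ambiguous pairs (A/T, C/G) are dropped by default
(configurable to keep when MAF < 0.4). Model variants absent from the
cohort are mean-imputed at dosage 2·MAF when the model stores a training
frequency, else dropped; per-model coverage is reported. A model with
weights but no usable variant raises a distinct error (not the same as an
empty model).

## Numerical choices

* Robust regression: Huber ψ, tuning 1.345, scale by normalized MAD,
  convergence on coefficients at 1e-8, 50 iterations max (statsmodels RLM
  underneath); p-values from t with n − k df. As the tuning constant → ∞
  the fit equals OLS to 1e-8.
* TWAS denominator instability: the regularized quadratic form must exceed
  1e-6 (relative to ‖w‖²); otherwise the gene is flagged unstable and given
  p = 1.
* EBM pairwise covariances with fewer than 30 complete genes fall back to 0
  with a warning (Fisher behavior for that pair).
* HMP adjusted p is clipped to (1e-300, 1]; k = 1 returns the input p for
  every combiner.
* GSEA ties: gene-id lexicographic order, so rankings are deterministic;
  permutation p has floor 1/(1 + n_perm).
* bedGraph export writes 0-based half-open single-base intervals, sorted,
  collapsing duplicate positions to the maximum value.

## Design choices where the design was open

* The EBM covariance is estimated from per-tissue association statistics
  across all genes — the natural analogue of Brown's data matrix in this
  setting — rather than from any per-gene resampling.
* Genes present in a subset of tissues are combined over the tissues they
  have (k varies per gene, minimum 1); a gene absent from one platform can
  still be the other platform's candidate but never consensus.
* One model store (1 Mb cis window) feeds both arms, and the cohort's own
  genotypes serve as the LD reference, which keeps the two arms maximally
  comparable on synthetic data; a separate summary-arm window (e.g. 0.5 Mb)
  is a configuration choice.
* Gene–locus proximity is anchored at the strand-aware TSS.
* The shipped consensus-gene table carries synthetic stand-in coordinates
  (files are labelled `*_synthetic_*`): gene names, chromosomes, section
  labels, directions and effect sizes are the printed inputs; positions are
  constructed to be consistent with the printed near/far partition, since
  real coordinates are not part of the inputs.

## Known limitations

Summary-level and individual-level statistics agree asymptotically (we
verify r ≥ 0.95 across genes when the LD panel is the cohort itself); with
an external panel or low model coverage the agreement degrades and is not
bounded here. The empirical Brown calibration assumes the across-gene
statistic distribution is a fair sample of the per-gene null dependence;
strong pervasive signal would bias the covariance upward. Cross-cohort
imputation comparison reports Fisher-transform exceedance descriptively and
makes no claim about real-data transferability.
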