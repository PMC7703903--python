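"""Synthetic cohort generator: genotypes, multi-tissue expression, phenotype, GWAS.

Every downstream stage of the pipeline (model training, GReX imputation,
individual- and summary-level association, meta-analysis) assumes a specific
generative structure: expression is a linear additive function of cis variant
dosages plus noise, eQTLs are partially shared across tissues, and the
quantitative phenotype receives its genetic signal only through the genetic
component of expression of a small set of modifier genes. This module
instantiates exactly that structure, so power and calibration of the whole
pipeline can be measured against known ground truth.

Genotypes are drawn from a Gaussian copula: per gene one LD block with AR(1)
latent correlation ``ld_rho`` between adjacent variants, thresholded at the
allele frequency to produce two haplotypes per sample. All randomness flows
from a single integer seed; each operation is a pure function of
``(config, seed)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimConfig",
    "VariantRecord",
    "GeneAnnotation",
    "DosageMatrix",
    "PhenotypeTable",
    "ExpressionMatrix",
    "TruthTable",
    "sim_gene_annotations",
    "sim_genotypes",
    "sim_multitissue_expression",
    "sim_phenotype",
    "make_summary_stats",
]

# non-ambiguous ref/alt pairs only: strand flips are then always resolvable,
# so simulated cohorts never lose variants to the ambiguous-allele filter
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

_GENES_PER_CHROM = 22
_CHROM_STRIDE = 10_000_000  # bp between gene starts sharing a chromosome
_GENE_LENGTH = 20_000
_VARIANT_SPREAD = 200_000   # variants within +/- this of the gene body


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    ``cis_h2`` is the proportion of expression variance explained by cis
    variants in tissues where the gene's eQTLs are active; residual variance
    makes each expressed gene total 1. ``tissue_sharing`` is the probability
    that a causal eQTL is active in any given tissue. ``n_train`` samples per
    tissue are flagged for model training so that association testing can
    exclude them, mirroring a cohort whose expression-training subjects are a
    subset of the GWAS subjects.
    """

    n_samples: int = 2_000
    n_genes: int = 300
    variants_per_gene: int = 30
    ld_rho: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_tissues: int = 3
    causal_variants_per_gene: int = 2
    cis_h2: float = 0.3
    tissue_sharing: float = 0.8
    n_modifier_genes: int = 10
    pheno_var_explained_per_gene: float = 0.01
    n_train: int = 500
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_samples, self.n_genes, self.variants_per_gene,
               self.n_tissues) <= 0:
            raise ValueError("counts must be positive")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        if not (0.0 <= self.cis_h2 < 1.0):
            raise ValueError("cis_h2 must lie in [0, 1)")
        if not (0.0 <= self.tissue_sharing <= 1.0):
            raise ValueError("tissue_sharing must lie in [0, 1]")
        if self.causal_variants_per_gene > self.variants_per_gene:
            raise ValueError("more causal variants than variants per gene")
        if self.n_modifier_genes > self.n_genes:
            raise ValueError("more modifier genes than genes")
        total = self.n_modifier_genes * self.pheno_var_explained_per_gene
        if total >= 1.0:
            raise ValueError(
                f"requested phenotype variance shares sum to {total} >= 1")
        if not (0 <= self.n_train < self.n_samples):
            raise ValueError("n_train must lie in [0, n_samples)")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class VariantRecord:
    id: str
    chrom: str
    pos: int          # 1-based
    ref: str
    alt: str          # effect / dosage-counted allele
    maf: float

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if not (0.0 < self.maf <= 0.5):
            raise ValueError("maf must lie in (0, 0.5]")


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    gene_type: str = "protein_coding"

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class DosageMatrix:
    """Sample x variant alt-allele dosage matrix with variant metadata."""

    sample_ids: list[str]
    variants: list[VariantRecord]
    dosages: np.ndarray  # (n_samples, n_variants), values in [0, 2]

    def __post_init__(self):
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.variants):
            raise ValueError("dosage matrix shape inconsistent with metadata")

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def subset_variants(self, idx: list[int]) -> "DosageMatrix":
        return DosageMatrix(self.sample_ids,
                            [self.variants[i] for i in idx],
                            self.dosages[:, idx])


@dataclass
class PhenotypeTable:
    """Per-sample phenotype and covariates.

    ``knorma`` is the standardized quantitative lung score (higher = milder
    disease). ``training_flags`` marks, per tissue, the samples used in
    expression-model training.
    """

    samples: pd.DataFrame                  # sample_id, knorma, sex, pc1..pc4
    training_flags: pd.DataFrame           # index sample_id, one bool col/tissue
    modifiers: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    def covariate_matrix(self) -> np.ndarray:
        """Design columns [sex, pc1..pc4] in sample order."""
        return self.samples[["sex", "pc1", "pc2", "pc3", "pc4"]].to_numpy(float)


@dataclass
class ExpressionMatrix:
    sample_ids: list[str]
    gene_ids: list[str]
    tissue: str
    values: np.ndarray  # (n_samples, n_genes)

    def gene_column(self, gene_id: str) -> np.ndarray:
        return self.values[:, self.gene_ids.index(gene_id)]


@dataclass
class TruthTable:
    """Ground truth of the generative model.

    ``effects`` holds one row per realized nonzero (gene, tissue, variant)
    effect on expression; ``shared`` the tissue-independent base effect of
    each causal variant; ``genetic_scores`` the standardized per-gene genetic
    expression component that feeds the phenotype.
    """

    effects: pd.DataFrame        # gene_id, tissue, variant_id, effect
    shared: pd.DataFrame         # gene_id, variant_id, beta
    genetic_scores: pd.DataFrame  # index sample_id, one column per gene


def _rng(cfg_seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg_seed, stage]))


def sim_gene_annotations(cfg: SimConfig) -> list[GeneAnnotation]:
    """Deterministic gene layout: genes spaced 10 Mb apart so cis windows of
    neighbouring genes never overlap; strand alternates."""
    cfg.validate()
    out = []
    for g in range(cfg.n_genes):
        chrom = f"chr{(g % _GENES_PER_CHROM) + 1}"
        start = (g // _GENES_PER_CHROM) * _CHROM_STRIDE + 5_000_000
        out.append(GeneAnnotation(
            gene_id=f"GENE{g:04d}", chrom=chrom, start=start,
            end=start + _GENE_LENGTH, strand="+" if g % 2 == 0 else "-"))
    return out


def sim_genotypes(cfg: SimConfig) -> DosageMatrix:
    """Draw hard-call dosages, one LD block per gene.

    Two latent haplotypes per sample follow an AR(1) Gaussian process along
    the block with lag-one correlation ``ld_rho``; the allele is carried when
    the latent value falls below the normal quantile of the variant's MAF.
    Thresholding attenuates the latent correlation, so realized adjacent-pair
    dosage correlation is somewhat below ``ld_rho``.
    """
    cfg.validate()
    rng = _rng(cfg.seed, 1)
    genes = sim_gene_annotations(cfg)
    n, m = cfg.n_samples, cfg.variants_per_gene
    sample_ids = [f"S{i:05d}" for i in range(n)]
    variants: list[VariantRecord] = []
    blocks = []
    lo, hi = cfg.maf_range
    rho = cfg.ld_rho
    for g, gene in enumerate(genes):
        span_lo = max(1, gene.start - _VARIANT_SPREAD)
        span_hi = gene.end + _VARIANT_SPREAD
        pos = np.sort(rng.choice(np.arange(span_lo, span_hi), size=m,
                                 replace=False))
        mafs = rng.uniform(lo, hi, size=m)
        pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
        for j in range(m):
            ref, alt = _ALLELE_PAIRS[pair_idx[j]]
            variants.append(VariantRecord(
                id=f"snp_{g:04d}_{j:02d}", chrom=gene.chrom, pos=int(pos[j]),
                ref=ref, alt=alt, maf=float(mafs[j])))
        thresh = stats.norm.ppf(mafs)
        hap_sum = np.zeros((n, m))
        for _ in range(2):  # two haplotypes
            z = np.empty((n, m))
            eps = rng.standard_normal((n, m))
            z[:, 0] = eps[:, 0]
            for j in range(1, m):
                z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho ** 2) * eps[:, j]
            hap_sum += (z < thresh)
        blocks.append(hap_sum)
    return DosageMatrix(sample_ids, variants, np.concatenate(blocks, axis=1))


def _block_slice(cfg: SimConfig, g: int) -> slice:
    m = cfg.variants_per_gene
    return slice(g * m, (g + 1) * m)


def sim_multitissue_expression(
    cfg: SimConfig, geno: DosageMatrix,
) -> tuple[list[ExpressionMatrix], TruthTable]:
    """Simulate expression with a sparse, partially shared cis-eQTL model.

    Per gene, ``causal_variants_per_gene`` variants in its block get a base
    effect shared across tissues; each (variant, tissue) pair is active with
    probability ``tissue_sharing``. In tissues with at least one active
    variant the genetic component is rescaled so realized cis heritability
    equals ``cis_h2`` exactly in-sample; residual noise is independent across
    tissues. Returned expression columns are standardized (mean 0, var 1).
    """
    cfg.validate()
    if geno.dosages.shape[1] != cfg.n_genes * cfg.variants_per_gene:
        raise ValueError("genotype matrix does not match config dimensions")
    rng = _rng(cfg.seed, 2)
    n = cfg.n_samples
    gene_ids = [f"GENE{g:04d}" for g in range(cfg.n_genes)]
    tissues = [f"tissue{t}" for t in range(cfg.n_tissues)]

    effect_rows = []
    shared_rows = []
    genetic_scores = np.zeros((n, cfg.n_genes))
    values = np.zeros((cfg.n_tissues, n, cfg.n_genes))

    for g in range(cfg.n_genes):
        block = geno.dosages[:, _block_slice(cfg, g)]
        causal = np.sort(rng.choice(cfg.variants_per_gene,
                                    size=cfg.causal_variants_per_gene,
                                    replace=False))
        beta = rng.standard_normal(cfg.causal_variants_per_gene)
        vids = [geno.variants[g * cfg.variants_per_gene + j].id for j in causal]
        for vid, b in zip(vids, beta):
            shared_rows.append((gene_ids[g], vid, float(b)))
        # tissue-independent genetic score used by the phenotype
        gfull = (block[:, causal] - block[:, causal].mean(0)) @ beta
        sd_full = gfull.std()
        genetic_scores[:, g] = gfull / sd_full if sd_full > 0 else 0.0

        active = rng.uniform(size=(cfg.n_tissues,
                                   cfg.causal_variants_per_gene)) < cfg.tissue_sharing
        for t in range(cfg.n_tissues):
            noise = rng.standard_normal(n)
            mask = active[t]
            gt = (block[:, causal[mask]] - block[:, causal[mask]].mean(0)) @ beta[mask]
            sd = gt.std()
            if cfg.cis_h2 > 0 and mask.any() and sd > 0:
                scale = np.sqrt(cfg.cis_h2) / sd
                expr = gt * scale + np.sqrt(1 - cfg.cis_h2) * noise
                for j, vid, b in zip(causal, vids, beta):
                    if active[t][list(causal).index(j)]:
                        effect_rows.append((gene_ids[g], tissues[t], vid,
                                            float(b * scale)))
            else:
                expr = noise
            expr = (expr - expr.mean()) / expr.std()
            values[t, :, g] = expr

    exprs = [ExpressionMatrix(geno.sample_ids, gene_ids, tissues[t],
                              values[t]) for t in range(cfg.n_tissues)]
    truth = TruthTable(
        effects=pd.DataFrame(effect_rows,
                             columns=["gene_id", "tissue", "variant_id",
                                      "effect"]),
        shared=pd.DataFrame(shared_rows,
                            columns=["gene_id", "variant_id", "beta"]),
        genetic_scores=pd.DataFrame(genetic_scores, index=geno.sample_ids,
                                    columns=gene_ids),
    )
    return exprs, truth


def sim_phenotype(cfg: SimConfig, geno: DosageMatrix,
                  truth: TruthTable) -> PhenotypeTable:
    """Quantitative phenotype with expression-mediated genetic effects.

    knorma = sum over modifier genes of lambda_g times the standardized
    genetic expression component, plus a small sex effect (0.05 SD), small
    loadings (0.02 SD) on 4 synthetic PCs, and standard-normal noise; the
    total is re-standardized, as befits a normalized score. Positive
    lambda_g means increased expression goes with milder disease
    ("protective"); the sign is recorded in the returned modifier table.
    """
    cfg.validate()
    rng = _rng(cfg.seed, 3)
    n = cfg.n_samples
    total_var = cfg.n_modifier_genes * cfg.pheno_var_explained_per_gene
    if total_var >= 1.0:
        raise ValueError("phenotype variance shares sum >= 1")

    gene_ids = list(truth.genetic_scores.columns)
    modifier_idx = np.sort(rng.choice(len(gene_ids), size=cfg.n_modifier_genes,
                                      replace=False))
    lam_sign = rng.choice([-1.0, 1.0], size=cfg.n_modifier_genes)
    lam = lam_sign * np.sqrt(cfg.pheno_var_explained_per_gene)

    sex = rng.integers(0, 2, size=n).astype(float)
    pcs = rng.standard_normal((n, 4))
    noise = rng.standard_normal(n)

    y = np.sqrt(max(1.0 - total_var, 0.0)) * noise
    for lam_g, gi in zip(lam, modifier_idx):
        y = y + lam_g * truth.genetic_scores.iloc[:, gi].to_numpy()
    y = y + 0.05 * (sex - sex.mean()) + pcs @ np.full(4, 0.02)
    y = (y - y.mean()) / y.std()

    samples = pd.DataFrame({
        "sample_id": geno.sample_ids, "knorma": y, "sex": sex,
        "pc1": pcs[:, 0], "pc2": pcs[:, 1], "pc3": pcs[:, 2], "pc4": pcs[:, 3],
    })
    flags = pd.DataFrame(False, index=geno.sample_ids,
                         columns=[f"tissue{t}" for t in range(cfg.n_tissues)])
    for t in range(cfg.n_tissues):
        train = rng.choice(n, size=cfg.n_train, replace=False)
        flags.iloc[train, t] = True
    modifiers = pd.DataFrame({
        "gene_id": [gene_ids[i] for i in modifier_idx],
        "lambda": lam,
        "direction": ["protective" if s > 0 else "harmful" for s in lam_sign],
    })
    return PhenotypeTable(samples=samples, training_flags=flags,
                          modifiers=modifiers)


def make_summary_stats(geno: DosageMatrix, pheno: PhenotypeTable):
    """Marginal GWAS of knorma on each variant with sex + 4 PC covariates.

    Covariates (plus intercept) are projected out of both phenotype and
    dosages; the marginal slope, its standard error and z = beta/se follow
    from the residualized regression. Variants with zero dosage variance are
    dropped with a warning. The effect allele is always alt. Two-sided p is
    taken from the normal approximation to the t statistic.
    """
    from .sum_assoc import GWASSummary

    if pheno.sample_ids != geno.sample_ids:
        raise ValueError("sample ids of genotypes and phenotypes differ")
    y = pheno.samples["knorma"].to_numpy(float)
    n = len(y)
    C = np.column_stack([np.ones(n), pheno.covariate_matrix()])
    k_cov = C.shape[1]
    # residualize via least squares projection
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    X = geno.dosages
    X_r = X - Q @ (Q.T @ X)

    xx = np.einsum("ij,ij->j", X_r, X_r)
    keep = xx > 1e-12
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} constant-dosage variants from "
                      "summary statistics")
    xy = X_r.T @ y_r
    beta = np.where(keep, xy / np.where(keep, xx, 1.0), np.nan)
    df = n - k_cov - 1
    rss = (y_r @ y_r) - beta ** 2 * xx
    sigma2 = rss / df
    se = np.sqrt(np.where(keep, sigma2 / np.where(keep, xx, 1.0), np.nan))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    rows = []
    for j, v in enumerate(geno.variants):
        if not keep[j]:
            continue
        rows.append((v.id, v.chrom, v.pos, v.alt, v.ref, float(z[j]), n,
                     float(p[j])))
    table = pd.DataFrame(rows, columns=["id", "chrom", "pos", "a1", "a2",
                                        "z", "n", "p"])
    return GWASSummary(table=table, n_dropped=n_dropped)
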