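"""Genetically regulated expression (GReX) imputation.

GReX of a gene in a sample is the weighted sum of alt-allele dosages over
the model's variants, T = sum_j w_j x_j, after harmonizing model effect
alleles with the cohort's ref/alt labels. Strand-ambiguous variant pairs
(A/T, C/G) are dropped by default because a strand flip cannot be told from
an allele swap; model variants missing from the cohort are mean-imputed at
dosage 2*MAF when the model stores a training frequency, otherwise the term
is dropped. A per-model harmonization report records all of this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .predictdb import ExpressionModel, ModelStore
from .simcohort import DosageMatrix, VariantRecord

__all__ = [
    "HarmonizationError",
    "HarmonizationReport",
    "GReXMatrix",
    "harmonize_alleles",
    "impute_grex",
    "compare_imputations",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


class HarmonizationError(ValueError):
    """No model variant could be matched to the cohort (distinct from a
    model that is empty by training)."""


@dataclass
class HarmonizationReport:
    matched: int = 0
    flipped: int = 0
    ambiguous_dropped: int = 0
    missing: int = 0
    mean_imputed: int = 0
    total: int = 0

    @property
    def coverage(self) -> float:
        return (self.matched + self.mean_imputed) / self.total if self.total else 0.0


@dataclass
class GReXMatrix:
    sample_ids: list[str]
    columns: list[tuple[str, str]]       # (gene_id, tissue)
    values: np.ndarray                   # (n_samples, n_columns)
    reports: dict[tuple[str, str], HarmonizationReport] = field(
        default_factory=dict)

    def column(self, gene_id: str, tissue: str) -> np.ndarray:
        return self.values[:, self.columns.index((gene_id, tissue))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=[f"{g}:{t}" for g, t in self.columns])


def _variant_index(variants: list[VariantRecord]):
    by_id = {v.id: (i, v) for i, v in enumerate(variants)}
    by_locus = {(v.chrom, v.pos, frozenset((v.ref, v.alt))): (i, v)
                for i, v in enumerate(variants)}
    return by_id, by_locus


def harmonize_alleles(model: ExpressionModel, variants: list[VariantRecord],
                      drop_ambiguous: bool = True,
                      ambiguous_maf_max: float = 0.4,
                      index=None):
    """Align model weights to a cohort's variants.

    Returns ``(cohort_indices, signed_weights, constant_offset, report)``.
    The weight sign flips when the model's effect allele matches the cohort
    ref allele (allele swap); matching is by variant id first, then by
    chrom:pos plus allele set. With ``drop_ambiguous=False`` an A/T or C/G
    variant is kept only when its stored MAF is below ``ambiguous_maf_max``.
    Unmatched variants with a stored model MAF contribute the constant
    2*MAF*weight (mean dosage imputation); otherwise the term is dropped.

    Raises :class:`HarmonizationError` when the model has weights but none
    can be used.
    """
    by_id, by_locus = _variant_index(variants) if index is None else index
    report = HarmonizationReport(total=len(model.weights))
    idx: list[int] = []
    w: list[float] = []
    offset = 0.0
    for entry in model.weights:
        ambiguous = _is_ambiguous(entry.effect_allele, entry.other_allele)
        if ambiguous and (drop_ambiguous or
                          (entry.maf is not None and
                           entry.maf >= ambiguous_maf_max)):
            report.ambiguous_dropped += 1
            continue
        hit = by_id.get(entry.variant_id)
        if hit is None:
            hit = by_locus.get((entry.chrom, entry.pos,
                                frozenset((entry.effect_allele,
                                           entry.other_allele))))
        if hit is None:
            if entry.maf is not None:
                offset += entry.weight * 2.0 * entry.maf
                report.mean_imputed += 1
            else:
                report.missing += 1
            continue
        i, v = hit
        if entry.effect_allele == v.alt and entry.other_allele == v.ref:
            idx.append(i)
            w.append(entry.weight)
            report.matched += 1
        elif entry.effect_allele == v.ref and entry.other_allele == v.alt:
            # effect-allele dosage is 2 - alt dosage: sign flip plus offset,
            # so GReX is exactly invariant to cohort ref/alt labelling
            idx.append(i)
            w.append(-entry.weight)
            offset += 2.0 * entry.weight
            report.matched += 1
            report.flipped += 1
        else:
            # alleles disagree even as a set cannot happen via by_locus; an
            # id match with different alleles is treated as missing
            if entry.maf is not None:
                offset += entry.weight * 2.0 * entry.maf
                report.mean_imputed += 1
            else:
                report.missing += 1
    if model.weights and report.matched == 0 and report.mean_imputed == 0:
        raise HarmonizationError(
            f"model {model.gene_id}/{model.tissue}: no variant matched")
    return idx, np.asarray(w, float), offset, report


def impute_grex(dosages: DosageMatrix, store: ModelStore,
                drop_ambiguous: bool = True) -> GReXMatrix:
    """Impute T[sample, (gene, tissue)] = sum_j w_j dosage[sample, j].

    Models whose variants are entirely unmatchable are skipped with a
    warning; a model with no weights yields an all-zero column.
    """
    index = _variant_index(dosages.variants)
    columns, cols, reports = [], [], {}
    skipped = 0
    for key in sorted(store.models):
        model = store.models[key]
        if model.is_empty:
            columns.append(key)
            cols.append(np.zeros(len(dosages.sample_ids)))
            reports[key] = HarmonizationReport()
            continue
        try:
            idx, w, offset, report = harmonize_alleles(
                model, dosages.variants, drop_ambiguous=drop_ambiguous,
                index=index)
        except HarmonizationError:
            skipped += 1
            continue
        t = dosages.dosages[:, idx] @ w + offset if idx else \
            np.full(len(dosages.sample_ids), offset)
        columns.append(key)
        cols.append(t)
        reports[key] = report
    if skipped:
        warnings.warn(f"skipped {skipped} models with no matchable variants")
    values = np.column_stack(cols) if cols else \
        np.zeros((len(dosages.sample_ids), 0))
    return GReXMatrix(sample_ids=list(dosages.sample_ids), columns=columns,
                      values=values, reports=reports)


def compare_imputations(a: pd.DataFrame, b: pd.DataFrame):
    """Compare two GReX imputations of the same genes on shared samples.

    Per shared gene key, the Pearson correlation r is computed on shared
    samples; z = atanh(r) is referred to the Fisher-transform null
    z ~ Normal(0, 1/(n-3)). Returns a dict with the per-gene table, mean R^2
    and the fraction of genes whose z exceeds the null 95th percentile.
    Zero-variance columns are skipped and counted.
    """
    samples = a.index.intersection(b.index)
    genes = [c for c in a.columns if c in set(b.columns)]
    n = len(samples)
    if n < 10:
        raise ValueError("need at least 10 shared samples")
    rows, skipped = [], 0
    for g in genes:
        x = a.loc[samples, g].to_numpy(float)
        y = b.loc[samples, g].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            skipped += 1
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append((g, r, r ** 2, np.arctanh(np.clip(r, -1 + 1e-15,
                                                      1 - 1e-15))))
    table = pd.DataFrame(rows, columns=["gene", "r", "r2", "fisher_z"])
    null_crit = stats.norm.ppf(0.95) / np.sqrt(n - 3)
    return {
        "table": table,
        "n_samples": n,
        "mean_r2": float(table["r2"].mean()) if len(table) else np.nan,
        "null_exceedance": float((table["fisher_z"] > null_crit).mean())
        if len(table) else np.nan,
        "skipped_zero_variance": skipped,
    }
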