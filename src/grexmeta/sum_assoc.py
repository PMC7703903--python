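"""Summary-statistic (FUSION-style) TWAS association.

The gene-level statistic combines marginal GWAS z-scores through the model
weights: z_twas = w'Z / sqrt(w'Rw), where R is the variant correlation
matrix from an LD reference panel, ridge-regularized as
(1-lambda) R + lambda I before the quadratic form. Model variants missing
from the GWAS or the panel are dropped from numerator and denominator, with
the coverage fraction reported. With a single variant the statistic reduces
exactly to that variant's GWAS z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import stats

from .predictdb import ModelStore

if TYPE_CHECKING:  # pragma: no cover
    from .simcohort import DosageMatrix

__all__ = ["GWASSummary", "ld_from_panel", "twas_z", "twas_scan",
           "DEFAULT_RIDGE"]

DEFAULT_RIDGE = 0.1
_EPS_UNSTABLE = 1e-6

# tolerated header dialects for GWAS summary tables
_COLUMN_ALIASES = {
    "id": ["id", "snp", "rsid", "variant_id", "markername"],
    "chrom": ["chrom", "chr", "chromosome"],
    "pos": ["pos", "bp", "position", "base_pair_location"],
    "a1": ["a1", "effect_allele", "alt", "ea"],
    "a2": ["a2", "other_allele", "ref", "oa", "nea"],
    "z": ["z", "zscore", "z_score", "stat"],
    "n": ["n", "sample_size", "nsamples"],
    "p": ["p", "pval", "p_value", "pvalue"],
}


@dataclass
class GWASSummary:
    """Per-variant marginal association summary (effect allele = a1)."""

    table: pd.DataFrame   # id, chrom, pos, a1, a2, z, n, p
    n_dropped: int = 0

    def __post_init__(self):
        missing = {"id", "chrom", "pos", "a1", "a2", "z", "n"} - \
            set(self.table.columns)
        if missing:
            raise ValueError(f"GWAS summary missing columns: {missing}")
        if "p" not in self.table.columns:
            self.table["p"] = 2.0 * stats.norm.sf(np.abs(self.table["z"]))

    def zmap(self) -> dict[str, tuple[str, str, float]]:
        return {r.id: (r.a1, r.a2, float(r.z))
                for r in self.table.itertuples()}

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def read_tsv(cls, path, column_map: dict[str, str] | None = None
                 ) -> "GWASSummary":
        df = pd.read_csv(path, sep="\t")
        lower = {c.lower(): c for c in df.columns}
        rename = {}
        for canon, aliases in _COLUMN_ALIASES.items():
            if column_map and canon in column_map:
                rename[column_map[canon]] = canon
                continue
            for a in aliases:
                if a in lower:
                    rename[lower[a]] = canon
                    break
        return cls(table=df.rename(columns=rename))


def ld_from_panel(panel: "DosageMatrix", variant_ids: list[str]) -> tuple[
        np.ndarray, list[str]]:
    """Pearson dosage-correlation matrix for a variant subset.

    Zero-variance variants are excluded with a warning. Returns (R, kept
    variant ids); the diagonal is exactly 1.
    """
    pos = {v.id: i for i, v in enumerate(panel.variants)}
    idx = [pos[v] for v in variant_ids if v in pos]
    kept_ids = [v for v in variant_ids if v in pos]
    X = panel.dosages[:, idx]
    sd = X.std(axis=0)
    ok = sd > 0
    if not ok.all():
        warnings.warn(f"excluded {int((~ok).sum())} zero-variance variants "
                      "from LD reference")
    X = X[:, ok]
    kept_ids = [v for v, k in zip(kept_ids, ok) if k]
    if X.shape[1] == 0:
        return np.zeros((0, 0)), []
    Xc = (X - X.mean(0)) / X.std(0)
    R = (Xc.T @ Xc) / X.shape[0]
    np.fill_diagonal(R, 1.0)
    return R, kept_ids


def regularize_ld(R: np.ndarray, ridge: float = DEFAULT_RIDGE) -> np.ndarray:
    """(1 - ridge) R + ridge I, keeping the unit diagonal."""
    return (1.0 - ridge) * R + ridge * np.eye(R.shape[0])


def twas_z(w: np.ndarray, z: np.ndarray, R: np.ndarray,
           ridge: float = DEFAULT_RIDGE) -> tuple[float, float]:
    """Gene-level z and two-sided normal p from weights, GWAS z and LD.

    Raises if the regularized quadratic form w'Rw is not positive enough
    to stabilize the denominator ("unstable" gene).
    """
    w = np.asarray(w, float)
    z = np.asarray(z, float)
    Rr = regularize_ld(np.asarray(R, float), ridge)
    denom2 = float(w @ Rr @ w)
    if denom2 <= _EPS_UNSTABLE * max(float(w @ w), 1e-300):
        raise FloatingPointError("unstable TWAS denominator")
    zt = float(w @ z) / np.sqrt(denom2)
    return zt, float(2.0 * stats.norm.sf(abs(zt)))


def twas_scan(store: ModelStore, gwas: GWASSummary, panel: "DosageMatrix",
              ridge: float = DEFAULT_RIDGE) -> pd.DataFrame:
    """One summary-level association record per retained (gene, tissue).

    Per model, weights are restricted to variants present (with consistent
    alleles) in both the GWAS and the LD panel; GWAS z signs flip for allele
    swaps. Genes with no usable variant are skipped and counted in
    ``DataFrame.attrs['skipped']``; numerically unstable genes are flagged.
    """
    zinfo = gwas.zmap()
    panel_ids = {v.id for v in panel.variants}
    records, skipped = [], 0
    for key in sorted(store.models):
        model = store.models[key]
        total = len(model.weights)
        w, zs, vids = [], [], []
        for entry in model.weights:
            if entry.variant_id not in zinfo or \
                    entry.variant_id not in panel_ids:
                continue
            a1, a2, zval = zinfo[entry.variant_id]
            if entry.effect_allele == a1 and entry.other_allele == a2:
                sign = 1.0
            elif entry.effect_allele == a2 and entry.other_allele == a1:
                sign = -1.0
            else:
                continue
            w.append(entry.weight)
            zs.append(sign * zval)
            vids.append(entry.variant_id)
        if not w:
            skipped += 1
            continue
        R, kept = ld_from_panel(panel, vids)
        keep_mask = [v in set(kept) for v in vids]
        w_arr = np.asarray(w)[keep_mask]
        z_arr = np.asarray(zs)[keep_mask]
        if w_arr.size == 0:
            skipped += 1
            continue
        coverage = w_arr.size / total if total else 0.0
        try:
            zt, p = twas_z(w_arr, z_arr, R, ridge)
            unstable = False
        except FloatingPointError:
            zt, p, unstable = 0.0, 1.0, True
        records.append((model.gene_id, model.tissue, zt, max(p, 1e-300),
                        "protective" if zt > 0 else "harmful", coverage,
                        unstable))
    out = pd.DataFrame(records, columns=["gene_id", "tissue", "z", "p",
                                         "direction", "coverage", "unstable"])
    out.attrs["skipped"] = skipped
    return out
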