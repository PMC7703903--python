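"""Combining correlated per-tissue association tests per gene.

All per-tissue tests derive from the same GWAS cohort, so their p-values
are dependent; three combiners that tolerate dependence are provided:

* harmonic mean p (HMP): raw HMP = (sum w) / (sum w_i/p_i); the
  asymptotically exact adjusted p refers 1/HMP to a Landau distribution
  with location ln(k) + 0.874368 and scale pi/2.
* empirical Brown's method (EBM): Fisher's X = -2 sum ln p calibrated to a
  scaled chi-square c * chisq_f, with scale and df from empirically
  estimated covariances of the -2 ln p transformed per-tissue statistics
  across genes (ECDF transform, pairwise-complete genes). With all
  covariances zero it reduces exactly to Fisher's method.
* omnibus test: chi-square of per-tissue TWAS z after whitening by the
  correlation matrix of predicted expression across tissues, with small
  eigenvalues dropped.

A gene is a per-platform candidate when both that platform's combined
p-values fall below the threshold (0.01), and a consensus modifier when all
four do.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .predictdb import ModelStore
from .sum_assoc import ld_from_panel, regularize_ld

__all__ = [
    "hmp_raw", "hmp_combine", "ebm_covariance", "ebm_combine",
    "omnibus_combine", "tissue_correlation", "combine_platform",
    "build_meta_table", "call_consensus", "candidate_counts",
    "signed_logp_matrix", "CONSENSUS_THRESHOLD",
]

CONSENSUS_THRESHOLD = 0.01
_HMP_LANDAU_LOC = 0.874368  # = 1 + ln(pi/2) - Euler gamma
_MIN_PAIRWISE_GENES = 30


def _check_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return p


def hmp_raw(p, weights=None) -> float:
    """Weighted harmonic mean of p-values (weights normalized to sum 1)."""
    p = _check_p(p)
    if weights is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.asarray(weights, float)
        w = w / w.sum()
    return float(1.0 / np.sum(w / p))


def hmp_combine(p, weights=None) -> float:
    """Asymptotically exact harmonic-mean combined p-value.

    For k = 1 the input p is returned unchanged. Otherwise the reciprocal
    of the raw HMP is referred to the Landau tail with location
    ln(k) + 0.874368 and scale pi/2.
    """
    p = _check_p(p)
    k = p.size
    if k == 1:
        return float(p[0])
    raw = hmp_raw(p, weights)
    adj = stats.landau.sf(1.0 / raw, loc=np.log(k) + _HMP_LANDAU_LOC,
                          scale=np.pi / 2)
    return float(min(max(adj, 1e-300), 1.0))


def ebm_covariance(stat_matrix: pd.DataFrame) -> np.ndarray:
    """Pairwise covariances of -2 ln p across tissues, estimated empirically.

    ``stat_matrix`` holds per-tissue association statistics (rows = genes,
    columns = tissues; NaN where a gene has no model). Each column is
    ECDF-transformed — the empirical two-sided survival fraction of |stat| —
    then mapped to w = -2 ln(ecdf). Off-diagonal entries come from the
    sample covariance over pairwise-complete genes; pairs with fewer than 30
    complete genes fall back to 0 with a warning. The diagonal is fixed at
    the theoretical variance 4 of a chi-square with 2 df.
    """
    cols = list(stat_matrix.columns)
    k = len(cols)
    transformed = {}
    for c in cols:
        s = stat_matrix[c].to_numpy(float)
        ok = np.isfinite(s)
        w = np.full(s.size, np.nan)
        a = np.abs(s[ok])
        # empirical survival P(|S| >= |s|), in (0, 1]
        ranks = stats.rankdata(-a, method="max")
        w[ok] = -2.0 * np.log(ranks / a.size)
        transformed[c] = w
    cov = np.zeros((k, k))
    np.fill_diagonal(cov, 4.0)
    for i in range(k):
        for j in range(i + 1, k):
            wi, wj = transformed[cols[i]], transformed[cols[j]]
            ok = np.isfinite(wi) & np.isfinite(wj)
            if ok.sum() < _MIN_PAIRWISE_GENES:
                warnings.warn(
                    f"fewer than {_MIN_PAIRWISE_GENES} pairwise-complete "
                    f"genes for ({cols[i]}, {cols[j]}); covariance set to 0")
                continue
            cov[i, j] = cov[j, i] = float(np.cov(wi[ok], wj[ok])[0, 1])
    return cov


def ebm_combine(p, cov: np.ndarray | None = None,
                stat_matrix: pd.DataFrame | None = None,
                tissues: list[str] | None = None) -> float:
    """Empirical Brown's combined p-value for one gene.

    X = -2 sum ln p is referred to c * chisq_f with f = 2 E^2 / Var,
    c = Var / (2 E), E = 2k and Var = 4k + 2 * sum_{i<j} cov_ij. The
    covariance matrix may be passed directly or estimated from
    ``stat_matrix`` (restricted to ``tissues``). k = 1 returns the single p.
    """
    p = _check_p(p)
    k = p.size
    if k == 1:
        return float(p[0])
    if cov is None:
        if stat_matrix is None:
            cov = np.zeros((k, k))
        else:
            sub = stat_matrix[tissues] if tissues is not None else stat_matrix
            cov = ebm_covariance(sub)
    cov = np.asarray(cov, float)
    if cov.shape != (k, k):
        raise ValueError("covariance matrix shape does not match k")
    X = float(-2.0 * np.sum(np.log(p)))
    E = 2.0 * k
    var = 4.0 * k + 2.0 * float(np.triu(cov, 1).sum())
    var = max(var, 1e-12)
    f = 2.0 * E ** 2 / var
    c = var / (2.0 * E)
    return float(min(max(stats.chi2.sf(X / c, f), 1e-300), 1.0))


def omnibus_combine(z, C: np.ndarray, drop_frac: float = 0.01) -> float:
    """Joint chi-square of per-tissue z-scores whitened by C.

    Eigencomponents of C with eigenvalue below ``drop_frac`` times the
    largest are dropped; the statistic sums (u'z)^2 / lambda over retained
    components and is referred to chi-square with df = number retained.
    """
    z = np.asarray(z, float)
    C = np.asarray(C, float)
    if z.size == 1:
        return float(2.0 * stats.norm.sf(abs(z[0])))
    lam, U = np.linalg.eigh((C + C.T) / 2.0)
    keep = (lam > 0) & (lam >= drop_frac * lam.max())
    if not keep.any():
        raise ValueError("all eigenvalues of the tissue-correlation matrix "
                         "were dropped")
    proj = U[:, keep].T @ z
    statv = float(np.sum(proj ** 2 / lam[keep]))
    return float(min(max(stats.chi2.sf(statv, int(keep.sum())), 1e-300), 1.0))


def tissue_correlation(store: ModelStore, gene_id: str, tissues: list[str],
                       panel, ridge: float = 0.1) -> np.ndarray:
    """Correlation of predicted expression across tissues for one gene.

    C_ij = w_i' R w_j / sqrt(w_i' R w_i * w_j' R w_j) with R the
    (regularized) LD matrix of the union of the tissues' model variants in
    the reference panel. Tissues whose weights have no panel coverage get
    identity rows.
    """
    union: list[str] = []
    for t in tissues:
        m = store.get(gene_id, t)
        if m is not None:
            union.extend(w.variant_id for w in m.weights)
    union = sorted(set(union))
    R, kept = ld_from_panel(panel, union)
    pos = {v: i for i, v in enumerate(kept)}
    k = len(tissues)
    W = np.zeros((k, len(kept)))
    for ti, t in enumerate(tissues):
        m = store.get(gene_id, t)
        if m is None:
            continue
        for w in m.weights:
            if w.variant_id in pos:
                W[ti, pos[w.variant_id]] = w.weight
    if len(kept) == 0:
        return np.eye(k)
    Rr = regularize_ld(R, ridge)
    G = W @ Rr @ W.T
    d = np.sqrt(np.diag(G))
    C = np.eye(k)
    ok = d > 0
    for i in range(k):
        for j in range(k):
            if i != j and ok[i] and ok[j]:
                C[i, j] = G[i, j] / (d[i] * d[j])
    return C


def combine_platform(assoc: pd.DataFrame, method: str,
                     store: ModelStore | None = None, panel=None,
                     stat_col: str = "stat") -> pd.DataFrame:
    """Per-gene HMP plus correlation-adjusted combination for one platform.

    ``method`` is "ebm" (individual-level arm) or "omnibus" (summary-level
    arm; requires ``store`` and ``panel`` for the per-gene tissue
    correlation). Genes are combined over however many tissues they have
    (k >= 1). Returns one row per gene with hmp_p, corradj_p, k_tissues and
    the mean effect (beta or z).
    """
    if method not in ("ebm", "omnibus"):
        raise ValueError("method must be 'ebm' or 'omnibus'")
    effect_col = "beta" if "beta" in assoc.columns else "z"
    stat_matrix = assoc.pivot_table(index="gene_id", columns="tissue",
                                    values=stat_col)
    cov_all = ebm_covariance(stat_matrix) if method == "ebm" else None
    tissue_order = list(stat_matrix.columns)
    tissue_pos = {t: i for i, t in enumerate(tissue_order)}

    rows = []
    for gene_id, sub in assoc.groupby("gene_id", sort=True):
        sub = sub[~sub.get("degenerate", pd.Series(False, index=sub.index))]
        if len(sub) == 0:
            continue
        p = sub["p"].to_numpy(float)
        tissues = list(sub["tissue"])
        hmp_p = hmp_combine(p)
        if method == "ebm":
            idx = [tissue_pos[t] for t in tissues]
            cov = cov_all[np.ix_(idx, idx)]
            adj = ebm_combine(p, cov=cov)
        else:
            C = tissue_correlation(store, gene_id, tissues, panel)
            adj = omnibus_combine(sub[stat_col].to_numpy(float), C)
        rows.append((gene_id, hmp_p, adj, len(sub),
                     float(sub[effect_col].mean())))
    return pd.DataFrame(rows, columns=["gene_id", "hmp_p", "corradj_p",
                                       "k_tissues", "mean_effect"])


def build_meta_table(predixcan_meta: pd.DataFrame,
                     twas_meta: pd.DataFrame) -> pd.DataFrame:
    """Merge the two platform combinations into one row per gene.

    Columns follow the four-test naming: hmp/corradj per platform. A gene
    missing from a platform has NaN there and is ineligible for consensus
    but can still be a candidate on the platform where it is present.
    BH-adjusted q-values are added for each combined p as a convenience.
    """
    a = predixcan_meta.rename(columns={
        "hmp_p": "hmp_predixcan", "corradj_p": "ebm_predixcan",
        "k_tissues": "k_predixcan", "mean_effect": "mean_beta"})
    b = twas_meta.rename(columns={
        "hmp_p": "hmp_twas", "corradj_p": "omnibus_twas",
        "k_tissues": "k_twas", "mean_effect": "mean_z"})
    meta = a.merge(b, on="gene_id", how="outer")
    pcols = ["hmp_predixcan", "ebm_predixcan", "hmp_twas", "omnibus_twas"]
    meta["max_meta_p"] = meta[pcols].max(axis=1)
    for c in pcols:
        ok = meta[c].notna()
        q = np.full(len(meta), np.nan)
        if ok.any():
            q[ok.to_numpy()] = multipletests(meta.loc[ok, c], method="fdr_bh")[1]
        meta[f"{c}_q"] = q
    return meta


def call_consensus(meta: pd.DataFrame,
                   threshold: float = CONSENSUS_THRESHOLD) -> pd.DataFrame:
    """Flag per-platform candidates and consensus modifier genes.

    A PrediXcan candidate has both hmp_predixcan and ebm_predixcan below
    the threshold; a TWAS candidate both hmp_twas and omnibus_twas; a
    consensus gene all four. The union of the two candidate sets is flagged
    as ``candidate``.
    """
    out = meta.copy()
    out["predixcan_candidate"] = (
        (out["hmp_predixcan"] < threshold) &
        (out["ebm_predixcan"] < threshold)).fillna(False)
    out["twas_candidate"] = (
        (out["hmp_twas"] < threshold) &
        (out["omnibus_twas"] < threshold)).fillna(False)
    out["candidate"] = out["predixcan_candidate"] | out["twas_candidate"]
    out["consensus"] = out["predixcan_candidate"] & out["twas_candidate"]
    return out


def candidate_counts(called: pd.DataFrame) -> dict[str, int]:
    """Set arithmetic over the called candidate flags."""
    a = int(called["predixcan_candidate"].sum())
    b = int(called["twas_candidate"].sum())
    both = int(called["consensus"].sum())
    union = int(called["candidate"].sum())
    assert union == a + b - both
    return {"predixcan": a, "twas": b, "consensus": both, "union": union}


def signed_logp_matrix(assoc: pd.DataFrame) -> pd.DataFrame:
    """Gene x tissue matrix of sign(effect) * -log10(p); NaN where a gene
    has no model in a tissue (the blank cells of a clustering heatmap)."""
    effect_col = "beta" if "beta" in assoc.columns else "z"
    df = assoc.copy()
    df["signed_logp"] = np.sign(df[effect_col]) * (-np.log10(df["p"]))
    return df.pivot_table(index="gene_id", columns="tissue",
                          values="signed_logp")
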