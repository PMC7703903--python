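"""Pre-ranked gene-set enrichment on the meta-analysis ranking.

Genes are ranked by -log10 of the maximal p-value between a platform's two
meta-analysis methods (the score is therefore nonnegative and one-tailed).
The enrichment score is the classic weighted Kolmogorov-Smirnov running
sum: a hit at position i increments by |score_i|^exponent normalized by the
sum over set hits, a miss decrements by 1/(N - N_hits); ES is the signed
maximum deviation and the leading edge the set members up to the extremum.
The null is gene-label permutation (random same-size sets), one-sided by ES
sign, with NES = ES / mean(|same-sign null ES|) and BH adjustment across
sets.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = ["read_gmt", "rank_genes", "enrichment_score", "preranked_gsea"]


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def rank_genes(meta: pd.DataFrame, platform: str,
               protein_coding_only: bool = False,
               gene_types: pd.Series | None = None) -> pd.DataFrame:
    """Ranked list for one platform: score = -log10(max of its two combined
    p-values), descending; ties broken by gene id lexicographic order."""
    if platform == "predixcan":
        cols = ["hmp_predixcan", "ebm_predixcan"]
    elif platform == "twas":
        cols = ["hmp_twas", "omnibus_twas"]
    else:
        raise ValueError("platform must be 'predixcan' or 'twas'")
    df = meta[["gene_id"] + cols].dropna()
    if len(df) == 0:
        raise ValueError("no genes with combined p-values for this platform")
    if protein_coding_only and gene_types is not None:
        coding = set(gene_types[gene_types == "protein_coding"].index)
        df = df[df["gene_id"].isin(coding)]
    out = pd.DataFrame({"gene_id": df["gene_id"],
                        "score": -np.log10(df[cols].max(axis=1))})
    out = out.sort_values(["score", "gene_id"],
                          ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)


def enrichment_score(ranked: pd.DataFrame, gene_set, exponent: float = 1.0):
    """Weighted KS enrichment score for one gene set.

    Returns ``(es, running_sum, leading_edge)``; for positive ES the leading
    edge is the set members at or before the running-sum maximum.
    """
    genes = ranked["gene_id"].to_numpy()
    scores = np.abs(ranked["score"].to_numpy(float))
    hit = np.isin(genes, list(gene_set))
    n = len(genes)
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValueError("gene set is disjoint from the ranked list")
    if n_hits == n:
        raise ValueError("gene set covers the entire ranked list")
    w = scores ** exponent
    hit_total = w[hit].sum()
    if hit_total == 0:  # all hit scores zero: fall back to unweighted hits
        step_hit = np.where(hit, 1.0 / n_hits, 0.0)
    else:
        step_hit = np.where(hit, w / hit_total, 0.0)
    step_miss = np.where(hit, 0.0, 1.0 / (n - n_hits))
    running = np.cumsum(step_hit - step_miss)
    i_ext = int(np.argmax(np.abs(running)))
    es = float(running[i_ext])
    if es >= 0:
        leading = [g for g, h in zip(genes[:i_ext + 1], hit[:i_ext + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[i_ext:], hit[i_ext:]) if h]
    return es, running, leading


def preranked_gsea(ranked: pd.DataFrame, sets: dict[str, list[str]],
                   n_perm: int = 1000, seed: int = 0, exponent: float = 1.0,
                   min_size: int = 5, max_size: int = 500) -> pd.DataFrame:
    """Permutation pre-ranked GSEA over a gene-set collection.

    The null for a set of size m is the ES of m genes sampled uniformly
    without replacement from the ranked list. p = (1 + #{same-sign null with
    |ES_null| >= |ES|}) / (1 + n_perm), NES = ES / mean |same-sign null ES|.
    Negative-ES records are flagged as depletion (the ranking is one-tailed).
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives very coarse p-values")
    rng = np.random.default_rng(seed)
    genes = ranked["gene_id"].to_numpy()
    universe = set(genes)
    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for name, members in sets.items():
        inlist = sorted(set(members) & universe)
        m = len(inlist)
        if not (min_size <= m <= max_size) or m == len(genes):
            continue
        es, _, leading = enrichment_score(ranked, inlist, exponent)
        if m not in null_cache:
            null = np.empty(n_perm)
            for b in range(n_perm):
                samp = rng.choice(genes, size=m, replace=False)
                null[b], _, _ = enrichment_score(ranked, samp, exponent)
            null_cache[m] = null
        null = null_cache[m]
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        exceed = int(np.sum(np.abs(same) >= abs(es)))
        p = (1 + exceed) / (1 + n_perm)
        denom = np.mean(np.abs(same)) if same.size else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 \
            else np.nan
        rows.append((name, m, es, nes, p, ",".join(leading), es < 0))
    out = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p",
                                      "leading_edge", "depletion"])
    if len(out):
        out["padj"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["padj"] = []
    return out
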