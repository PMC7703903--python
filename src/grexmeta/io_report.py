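"""Readers/writers, GWAS-proximity annotation, comparison tables, bedGraph
export, and the end-to-end pipeline driver.

Every table writer has a matching reader and round-trips losslessly to 12
significant digits; every artifact a pipeline run writes is listed in a
manifest with its SHA-256 checksum, so a run is fully auditable and a re-run
with the same config and seed is byte-identical apart from timestamps (which
are therefore kept out of the artifacts themselves).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import grex as grex_mod
from . import ind_assoc, predictdb, simcohort, sum_assoc, tissue_meta
from .predictdb import ModelStore, WeightEntry, ExpressionModel
from .simcohort import (DosageMatrix, GeneAnnotation, PhenotypeTable,
                        SimConfig, VariantRecord)

logger = logging.getLogger("grexmeta")

__all__ = [
    "GwasLocus", "ReportBundle", "PipelineConfig",
    "annotate_gwas_proximity", "gwas_vs_imputation_table", "export_bedgraph",
    "run_pipeline", "load_consensus_gene_fixture", "load_gwas_locus_fixture",
    "write_dosage_tsv", "read_dosage_tsv", "write_phenotype_tsv",
    "read_phenotype_tsv", "write_model_store", "read_model_store",
]

_FLOAT_FMT = "%.12g"


@dataclass(frozen=True)
class GwasLocus:
    label: str
    chrom: str
    position: int  # 1-based anchor (lead-variant position)


@dataclass
class ReportBundle:
    manhattan: pd.DataFrame
    gwas_vs_imputation: pd.DataFrame
    gwas_vs_imputation_r: float
    consensus_table: pd.DataFrame
    candidate_counts: dict
    manifest: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# table writers/readers

def write_dosage_tsv(geno: DosageMatrix, path) -> None:
    meta = pd.DataFrame({
        "id": [v.id for v in geno.variants],
        "chrom": [v.chrom for v in geno.variants],
        "pos": [v.pos for v in geno.variants],
        "ref": [v.ref for v in geno.variants],
        "alt": [v.alt for v in geno.variants],
        "maf": [v.maf for v in geno.variants],
    })
    dat = pd.DataFrame(geno.dosages.T, columns=geno.sample_ids)
    pd.concat([meta, dat], axis=1).to_csv(path, sep="\t", index=False,
                                          float_format=_FLOAT_FMT)


def read_dosage_tsv(path) -> DosageMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["id", "chrom", "pos", "ref", "alt", "maf"]
    sample_ids = [c for c in df.columns if c not in meta_cols]
    variants = [VariantRecord(id=r.id, chrom=r.chrom, pos=int(r.pos),
                              ref=r.ref, alt=r.alt, maf=float(r.maf))
                for r in df[meta_cols].itertuples()]
    return DosageMatrix(sample_ids, variants,
                        df[sample_ids].to_numpy(float).T)


def write_phenotype_tsv(pheno: PhenotypeTable, path) -> None:
    df = pheno.samples.copy()
    for t in pheno.training_flags.columns:
        df[f"train_{t}"] = pheno.training_flags[t].to_numpy()
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_phenotype_tsv(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t")
    train_cols = [c for c in df.columns if c.startswith("train_")]
    flags = df[train_cols].copy()
    flags.columns = [c[len("train_"):] for c in train_cols]
    flags.index = df["sample_id"]
    return PhenotypeTable(samples=df.drop(columns=train_cols),
                          training_flags=flags)


def write_model_store(store: ModelStore, weights_path, summary_path) -> None:
    store.weight_table().to_csv(weights_path, sep="\t", index=False,
                                float_format=_FLOAT_FMT)
    store.summary_table().to_csv(summary_path, sep="\t", index=False,
                                 float_format=_FLOAT_FMT)


def read_model_store(weights_path, summary_path) -> ModelStore:
    wt = pd.read_csv(weights_path, sep="\t")
    sm_ = pd.read_csv(summary_path, sep="\t")
    store = ModelStore()
    grouped = {k: v for k, v in wt.groupby(["gene_id", "tissue"])}
    for r in sm_.itertuples():
        key = (r.gene_id, r.tissue)
        weights = []
        if key in grouped:
            for w in grouped[key].itertuples():
                maf = None if pd.isna(w.maf) else float(w.maf)
                weights.append(WeightEntry(
                    variant_id=w.variant_id, chrom=w.chrom, pos=int(w.pos),
                    effect_allele=w.effect_allele,
                    other_allele=w.other_allele, weight=float(w.weight),
                    maf=maf))
        store.add(ExpressionModel(
            gene_id=r.gene_id, tissue=r.tissue, weights=weights,
            cv_r2=float(r.cv_r2), cv_p=float(r.cv_p),
            n_train=int(r.n_train), cis_window=int(r.cis_window)))
    return store


# ---------------------------------------------------------------------------
# shipped fixtures (positions are synthetic stand-ins; see file headers)

def load_consensus_gene_fixture() -> pd.DataFrame:
    with resources.files("grexmeta.data").joinpath(
            "consensus_genes_synthetic_positions.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_gwas_locus_fixture() -> list[GwasLocus]:
    with resources.files("grexmeta.data").joinpath(
            "gwas_loci_synthetic.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return [GwasLocus(label=r.label, chrom=str(r.chrom),
                      position=int(r.position)) for r in df.itertuples()]


# ---------------------------------------------------------------------------
# reporting operations

def annotate_gwas_proximity(genes: list[GeneAnnotation],
                            loci: list[GwasLocus],
                            window_bp: int = 1_000_000) -> pd.DataFrame:
    """Flag genes whose strand-aware TSS lies within ``window_bp`` (closed
    boundary) of any locus anchor on the same chromosome."""
    if not loci:
        raise ValueError("need at least one GWAS locus")
    rows = []
    for g in genes:
        near, best = False, None
        for loc in loci:
            if loc.chrom != g.chrom:
                continue
            d = abs(g.tss - loc.position)
            if best is None or d < best:
                best = d
            if d <= window_bp:
                near = True
        rows.append((g.gene_id, g.chrom, g.tss, near, best))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss",
                                       "near_gwas", "min_distance"])


def gwas_vs_imputation_table(store: ModelStore, gwas: "sum_assoc.GWASSummary",
                             meta: pd.DataFrame):
    """Per gene: min GWAS p over variants in any retained model vs the max
    meta p; plus the Pearson r of the two -log10 p columns."""
    pmap = dict(zip(gwas.table["id"], gwas.table["p"]))
    per_gene: dict[str, float] = {}
    for m in store:
        for w in m.weights:
            if w.variant_id in pmap:
                p = pmap[w.variant_id]
                if m.gene_id not in per_gene or p < per_gene[m.gene_id]:
                    per_gene[m.gene_id] = p
    n_excluded = len(set(store.genes())) - len(per_gene)
    df = pd.DataFrame({"gene_id": list(per_gene),
                       "min_gwas_p": list(per_gene.values())})
    df = df.merge(meta[["gene_id", "max_meta_p"]], on="gene_id", how="inner")
    df = df.dropna(subset=["max_meta_p"])
    if len(df) >= 3:
        r = float(np.corrcoef(-np.log10(df["min_gwas_p"]),
                              -np.log10(df["max_meta_p"]))[0, 1])
    else:
        r = np.nan
    df.attrs["excluded_no_gwas_coverage"] = n_excluded
    return df, r


def export_bedgraph(values: pd.DataFrame, out,
                    track_name: str = "gwas_logp") -> None:
    """Write per-variant -log10 p as a bedGraph custom track.

    ``values`` needs columns chrom, pos (1-based), p. Intervals are 0-based
    half-open single bases [pos-1, pos); output is sorted by chrom then
    start; duplicate positions collapse to the maximum value with a warning.
    """
    df = values[["chrom", "pos", "p"]].copy()
    df["value"] = -np.log10(df["p"].astype(float)) + 0.0  # avoid -0.0 at p=1
    before = len(df)
    df = df.groupby(["chrom", "pos"], as_index=False)["value"].max()
    if len(df) < before:
        warnings.warn(f"collapsed {before - len(df)} duplicate positions to "
                      "their maximum value")
    df = df.sort_values(["chrom", "pos"], kind="mergesort")
    with open(out, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        for r in df.itertuples():
            fh.write(f"{r.chrom}\t{r.pos - 1}\t{r.pos}\t{r.value:.6g}\n")


# ---------------------------------------------------------------------------
# end-to-end pipeline

@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-cohort pipeline run.

    One model store (cis window ``window_bp``) feeds both the
    individual-level and the summary-level arm, and the cohort's own
    genotypes serve as LD reference for the summary arm.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    window_bp: int = 1_000_000
    folds: int = 10
    r2_min: float = predictdb.DEFAULT_R2_MIN
    p_max: float = predictdb.DEFAULT_P_MAX
    consensus_threshold: float = tissue_meta.CONSENSUS_THRESHOLD
    ridge: float = sum_assoc.DEFAULT_RIDGE
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        if "maf_range" in sim_raw:
            sim_raw["maf_range"] = tuple(sim_raw["maf_range"])
        return cls(sim=SimConfig(**sim_raw), **raw)

    def to_yaml(self, path) -> None:
        # outdir is a run location, not part of the scientific config: it is
        # excluded so re-runs into different directories stay byte-identical
        d = {"sim": {**self.sim.__dict__,
                     "maf_range": list(self.sim.maf_range)},
             **{k: v for k, v in self.__dict__.items()
                if k not in ("sim", "outdir")}}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps({"sim": self.sim.__dict__,
                              **{k: v for k, v in self.__dict__.items()
                                 if k not in ("sim", "outdir")}},
                             sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full synthetic workflow and return all stage outputs.

    Stages: cohort simulation -> per-tissue elastic-net training (on each
    tissue's flagged training samples) and imputable-gene filtering -> GReX
    imputation -> robust individual-level association (training overlap
    excluded) and summary-level TWAS (GWAS from the same cohort, LD from the
    cohort genotypes) -> four-way meta-analysis and consensus calls ->
    report tables. When ``config.outdir`` is set every artifact is written
    with a checksum manifest.
    """
    cfg = config.sim
    cfg.validate()
    logger.info("stage simulate: n=%d genes=%d tissues=%d", cfg.n_samples,
                cfg.n_genes, cfg.n_tissues)
    genes = simcohort.sim_gene_annotations(cfg)
    geno = simcohort.sim_genotypes(cfg)
    exprs, truth = simcohort.sim_multitissue_expression(cfg, geno)
    pheno = simcohort.sim_phenotype(cfg, geno, truth)
    gwas = simcohort.make_summary_stats(geno, pheno)

    logger.info("stage train: %d tissues x %d genes", cfg.n_tissues,
                cfg.n_genes)
    store = ModelStore(metadata={"config_hash": config.config_hash()})
    for t, expr in enumerate(exprs):
        train = [s for s in geno.sample_ids
                 if bool(pheno.training_flags.loc[s, expr.tissue])]
        tissue_store = predictdb.train_tissue_models(
            expr, geno, genes, train_samples=train,
            window_bp=config.window_bp, folds=config.folds,
            seed=cfg.seed + 1000 * (t + 1))
        for m in predictdb.filter_models(tissue_store, config.r2_min,
                                         config.p_max):
            store.add(m)
    logger.info("stage train done: %d retained models", len(store))

    logger.info("stage impute")
    grex = grex_mod.impute_grex(geno, store)

    logger.info("stage associate (individual + summary)")
    assoc_ind = ind_assoc.assoc_scan(grex, pheno)
    assoc_sum = sum_assoc.twas_scan(store, gwas, geno, ridge=config.ridge)

    logger.info("stage meta-analysis")
    meta_ind = tissue_meta.combine_platform(assoc_ind, "ebm")
    meta_sum = tissue_meta.combine_platform(assoc_sum, "omnibus",
                                            store=store, panel=geno,
                                            stat_col="z")
    meta = tissue_meta.build_meta_table(meta_ind, meta_sum)
    called = tissue_meta.call_consensus(meta, config.consensus_threshold)
    counts = tissue_meta.candidate_counts(called)
    logger.info("consensus genes: %d (union %d)", counts["consensus"],
                counts["union"])

    logger.info("stage report")
    ann = {g.gene_id: g for g in genes}
    manhattan = called[["gene_id", "hmp_predixcan", "ebm_predixcan",
                        "hmp_twas", "omnibus_twas", "max_meta_p",
                        "consensus"]].copy()
    manhattan.insert(1, "chrom", [ann[g].chrom for g in manhattan["gene_id"]])
    manhattan.insert(2, "tss", [ann[g].tss for g in manhattan["gene_id"]])
    gvi, gvi_r = gwas_vs_imputation_table(store, gwas, called)
    consensus_table = called[called["consensus"]].copy()
    bundle = ReportBundle(manhattan=manhattan, gwas_vs_imputation=gvi,
                          gwas_vs_imputation_r=gvi_r,
                          consensus_table=consensus_table,
                          candidate_counts=counts)

    result = {
        "config": config, "genes": genes, "geno": geno, "exprs": exprs,
        "truth": truth, "pheno": pheno, "gwas": gwas, "store": store,
        "grex": grex, "assoc_ind": assoc_ind, "assoc_sum": assoc_sum,
        "meta": called, "counts": counts,
        "signed_logp_ind": tissue_meta.signed_logp_matrix(assoc_ind),
        "signed_logp_sum": tissue_meta.signed_logp_matrix(assoc_sum),
        "report": bundle,
    }

    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_dosage_tsv(geno, out / "dosages.tsv")
        write_phenotype_tsv(pheno, out / "phenotype.tsv")
        for expr in exprs:
            pd.DataFrame(expr.values, index=expr.sample_ids,
                         columns=expr.gene_ids).to_csv(
                out / f"expression_{expr.tissue}.tsv", sep="\t",
                float_format=_FLOAT_FMT)
        gwas.write_tsv(out / "gwas_summary.tsv")
        write_model_store(store, out / "model_weights.tsv",
                          out / "model_summary.tsv")
        grex.to_frame().to_csv(out / "grex.tsv", sep="\t",
                               float_format=_FLOAT_FMT)
        assoc_ind.to_csv(out / "assoc_individual.tsv", sep="\t", index=False,
                         float_format=_FLOAT_FMT)
        assoc_sum.to_csv(out / "assoc_summary.tsv", sep="\t", index=False,
                         float_format=_FLOAT_FMT)
        called.to_csv(out / "meta_results.tsv", sep="\t", index=False,
                      float_format=_FLOAT_FMT)
        result["signed_logp_ind"].to_csv(out / "signed_logp_predixcan.tsv",
                                         sep="\t", float_format=_FLOAT_FMT)
        result["signed_logp_sum"].to_csv(out / "signed_logp_twas.tsv",
                                         sep="\t", float_format=_FLOAT_FMT)
        manhattan.to_csv(out / "manhattan.tsv", sep="\t", index=False,
                         float_format=_FLOAT_FMT)
        gvi.to_csv(out / "gwas_vs_imputation.tsv", sep="\t", index=False,
                   float_format=_FLOAT_FMT)
        export_bedgraph(gwas.table, out / "gwas_logp.bedGraph")
        config.to_yaml(out / "config.yaml")
        manifest = {p.name: _sha256(p) for p in sorted(out.iterdir())
                    if p.name != "manifest.json"}
        manifest["config_hash"] = config.config_hash()
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        bundle.manifest = manifest
    return result
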