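import numpy as np
import pytest

from grexmeta import predictdb
from grexmeta.simcohort import (SimConfig, sim_gene_annotations,
                                sim_genotypes, sim_multitissue_expression,
                                sim_phenotype, make_summary_stats)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Small cohort exercised by many unit tests; minutes-scale overall."""
    return SimConfig(n_samples=600, n_genes=25, variants_per_gene=15,
                     ld_rho=0.6, n_tissues=3, causal_variants_per_gene=2,
                     cis_h2=0.3, tissue_sharing=0.8, n_modifier_genes=4,
                     pheno_var_explained_per_gene=0.01, n_train=200, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    genes = sim_gene_annotations(small_cfg)
    geno = sim_genotypes(small_cfg)
    exprs, truth = sim_multitissue_expression(small_cfg, geno)
    pheno = sim_phenotype(small_cfg, geno, truth)
    gwas = make_summary_stats(geno, pheno)
    return {"cfg": small_cfg, "genes": genes, "geno": geno, "exprs": exprs,
            "truth": truth, "pheno": pheno, "gwas": gwas}


@pytest.fixture(scope="session")
def small_store(small_cohort):
    """Filtered per-tissue model stores merged over tissues."""
    store = predictdb.ModelStore()
    pheno = small_cohort["pheno"]
    for t, expr in enumerate(small_cohort["exprs"]):
        train = [s for s in small_cohort["geno"].sample_ids
                 if bool(pheno.training_flags.loc[s, expr.tissue])]
        tissue_store = predictdb.train_tissue_models(
            expr, small_cohort["geno"], small_cohort["genes"],
            train_samples=train, seed=7 + t)
        for m in predictdb.filter_models(tissue_store):
            store.add(m)
    return store


@pytest.fixture(scope="session")
def small_grex(small_cohort, small_store):
    from grexmeta import grex
    return grex.impute_grex(small_cohort["geno"], small_store)
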