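import numpy as np
import pandas as pd
import pytest

from multiprs import simulate


@pytest.fixture(scope="session")
def small_config():
    return simulate.CohortConfig(
        n_individuals={"white": 400, "black": 300, "asian": 200},
        m_variants=400,
        m_causal=50,
        ld_block_size=5,
        ld_rho=0.5,
        heritability_prs=0.10,
        relatedness_pairs=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def harmonized_sumstats(small_cohort):
    """Regression-mode SBP summary stats of the small cohort, QC'd and harmonized."""
    from multiprs import sumstats as ss_mod

    geno = small_cohort["genotypes"]
    ss = simulate.simulate_gwas_sumstats(
        geno,
        small_cohort["phenotypes"],
        np.ones(geno.n, dtype=bool),
        trait="sbp",
        seed=5,
    )
    panel = ss_mod.panel_variants(geno)
    qc, _ = ss_mod.qc_filter(ss.dropna(subset=["beta"]), panel)
    harm, _ = ss_mod.harmonize_alleles(qc, panel)
    return harm


def toy_sumstats(n=4, seed=0):
    """Tiny well-formed summary-statistic frame for unit tests."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, n + 1) * 1000,
            "effect_allele": ["A"] * n,
            "other_allele": ["G"] * n,
            "beta": rng.normal(size=n),
            "se": np.full(n, 0.1),
            "pval": rng.uniform(0.01, 0.99, n),
            "eaf": rng.uniform(0.1, 0.9, n),
            "n": 1000,
        }
    )
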