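"""Generator checks: Balding-Nichols moments, LD structure, heritability,
group variances, relatedness, and summary-statistic calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from multiprs import io, simulate
from multiprs.errors import ConfigurationError, InputError


class TestAncestralFrequencies:
    def test_degenerate_interval_gives_constant(self):
        f = simulate.simulate_ancestral_frequencies(50, (0.3, 0.3), seed=1)
        assert np.all(f == 0.3)

    def test_reversed_range_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate.simulate_ancestral_frequencies(10, (0.9, 0.1), seed=1)

    def test_same_seed_identical(self):
        a = simulate.simulate_ancestral_frequencies(100, seed=7)
        b = simulate.simulate_ancestral_frequencies(100, seed=7)
        assert np.array_equal(a, b)

    def test_uniform_mean(self):
        m = 10_000
        f = simulate.simulate_ancestral_frequencies(m, (0.05, 0.95), seed=2)
        se = (0.95 - 0.05) / np.sqrt(12 * m)
        assert abs(f.mean() - 0.5) < 3 * se


class TestPopulationFrequencies:
    def test_fst_domain(self):
        with pytest.raises(ConfigurationError):
            simulate.simulate_population_frequencies([0.5], fst=0.0)
        with pytest.raises(ConfigurationError):
            simulate.simulate_population_frequencies([0.5], fst=1.0)

    def test_zero_divergence_limit(self):
        p0 = np.full(200, 0.37)
        p = simulate.simulate_population_frequencies(p0, fst=1e-6, seed=3)
        assert np.max(np.abs(p - p0)) < 1e-2

    def test_beta_moments(self):
        # replicate draws at p=0.4, F=0.2: mean p, variance F p (1-p)
        p, F, reps = 0.4, 0.2, 10_000
        draws = simulate.simulate_population_frequencies(np.full(reps, p), F, seed=4)
        var_true = F * p * (1 - p)
        se_mean = np.sqrt(var_true / reps)
        assert abs(draws.mean() - p) < 3 * se_mean
        se_var = np.sqrt(2.0 / reps) * var_true  # rough normal-theory SE
        assert abs(draws.var() - var_true) < 4 * se_var

    def test_fst_monotonic_divergence(self):
        p0 = simulate.simulate_ancestral_frequencies(2000, seed=5)
        div = []
        for i, f in enumerate((0.01, 0.05, 0.2)):
            p = simulate.simulate_population_frequencies(p0, f, seed=50 + i)
            div.append(np.mean((p - p0) ** 2))
        assert div[0] < div[1] < div[2]


class TestGenotypes:
    def test_fixed_allele_gives_dosage_two(self):
        geno = simulate.simulate_genotypes(
            np.array([[1 - 1e-12, 0.5]]), np.ones((20, 1)), ld_block_size=1, seed=6
        )
        assert np.all(geno.dosages[:, 0] == 2)

    def test_sample_frequency_matches_population(self):
        p = np.array([[0.3, 0.6, 0.1]])
        n = 4000
        geno = simulate.simulate_genotypes(p, np.ones((n, 1)), ld_block_size=1, seed=7)
        freq = geno.allele_frequencies()
        se = np.sqrt(p[0] * (1 - p[0]) / (2 * n))
        assert np.all(np.abs(freq - p[0]) < 3.5 * se)

    def test_blocks_of_one_are_independent(self):
        p = np.full((1, 40), 0.5)
        geno = simulate.simulate_genotypes(p, np.ones((3000, 1)), ld_block_size=1, seed=8)
        r = np.corrcoef(geno.dosages.T)
        off = r[np.triu_indices(40, 1)]
        # mean off-diagonal r^2 of independent variants ~ 1/n
        assert np.mean(off**2) < 5.0 / 3000

    def test_within_block_r2_exceeds_between(self):
        p = np.full((1, 40), 0.5)
        geno = simulate.simulate_genotypes(
            p, np.ones((2000, 1)), ld_block_size=5, ld_rho=0.5, seed=9
        )
        r2 = np.corrcoef(geno.dosages.T) ** 2
        blocks = np.arange(40) // 5
        same = blocks[:, None] == blocks[None, :]
        iu = np.triu_indices(40, 1)
        within = r2[iu][same[iu]]
        between = r2[iu][~same[iu]]
        assert within.mean() > 10 * between.mean()

    def test_relatedness_pairs_share_haplotype(self):
        p = np.full((1, 500), 0.5)
        geno = simulate.simulate_genotypes(
            p, np.ones((40, 1)), ld_block_size=1, seed=10, relatedness_pairs=5
        )
        kin = simulate.grm_kinship(geno, groups=np.zeros(40, dtype=int))
        sib = [kin[2 * i, 2 * i + 1] for i in range(5)]
        other = kin[20:, 20:][np.triu_indices(20, 1)]
        assert min(sib) > 2.0 ** -4.5
        assert np.mean(other) < 2.0 ** -4.5

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InputError):
            simulate.simulate_genotypes(np.ones((2, 10)) * 0.5, np.ones((5, 3)) / 3)

    def test_identical_seed_identical_files(self, tmp_path, small_config):
        paths = []
        for name in ("a.tsv", "b.tsv"):
            res = simulate.simulate_cohort(small_config)
            p = tmp_path / name
            io.write_dosage_tsv(res["genotypes"], p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestPhenotypes:
    def test_noise_only_limit(self):
        cfg = simulate.CohortConfig(
            n_individuals={"white": 3000, "black": 3000, "asian": 100},
            m_variants=50,
            m_causal=5,
            heritability_prs=0.0,
            covariate_effects={"age": 0, "age2": 0, "sex": 0, "bmi": 0, "smoking": 0},
            med_use_prob={"white": 0.0, "black": 0.0, "asian": 0.0},
            group_residual_sd={"white": 16.0, "black": 20.0, "asian": 16.0},
            seed=12,
        )
        res = simulate.simulate_cohort(cfg)
        ph = res["phenotypes"]
        for g, sd in (("white", 16.0), ("black", 20.0)):
            s = ph.loc[ph.group == g, "sbp"].std()
            n = (ph.group == g).sum()
            se = sd / np.sqrt(2 * n)
            assert abs(s - sd) < 3 * se

    def test_zero_effects_with_positive_h2_rejected(self, small_cohort, small_config):
        geno = small_cohort["genotypes"]
        zeros = (np.zeros(geno.m), np.zeros(geno.m))
        with pytest.raises(ConfigurationError):
            simulate.simulate_phenotypes(geno, zeros, small_config, seed=1)

    def test_heritability_recovered_by_regression(self):
        cfg = simulate.CohortConfig(
            n_individuals={"white": 2500, "black": 1500, "asian": 1000},
            m_variants=300,
            m_causal=60,
            heritability_prs=0.10,
            med_use_prob={"white": 0.0, "black": 0.0, "asian": 0.0},
            seed=13,
        )
        res = simulate.simulate_cohort(cfg)
        ph, truth = res["phenotypes"], res["truth"]
        g = truth["g_sbp"]
        # R^2 of trait residual (after covariates) on the true genetic value
        import statsmodels.api as sm

        covars = np.column_stack(
            [np.ones(len(ph)), ph.age, ph.age**2, ph.sex, ph.bmi]
        )
        resid = ph.sbp - covars @ np.linalg.lstsq(covars, ph.sbp, rcond=None)[0]
        r2 = sm.OLS(resid, sm.add_constant(g)).fit().rsquared
        assert abs(r2 - 0.10) < 0.02

    def test_group_variance_ratio_recovered(self):
        cfg = simulate.CohortConfig(
            n_individuals={"white": 4000, "black": 4000, "asian": 100},
            m_variants=100,
            m_causal=20,
            heritability_prs=0.0,
            covariate_effects={"age": 0, "age2": 0, "sex": 0, "bmi": 0, "smoking": 0},
            med_use_prob={"white": 0.0, "black": 0.0, "asian": 0.0},
            group_residual_sd={"white": 16.0, "black": 17.9, "asian": 16.0},
            seed=14,
        )
        ph = simulate.simulate_cohort(cfg)["phenotypes"]
        ratio = ph.loc[ph.group == "black", "sbp"].var() / ph.loc[ph.group == "white", "sbp"].var()
        target = (17.9 / 16.0) ** 2  # the ~25%-higher-variance scenario
        assert abs(ratio - target) / target < 0.10


@pytest.fixture(scope="module")
def null_cohort():
    cfg = simulate.CohortConfig(
        n_individuals={"white": 1500, "black": 100, "asian": 100},
        m_variants=400,
        m_causal=4,
        ld_block_size=1,
        heritability_prs=0.0,
        seed=15,
    )
    return simulate.simulate_cohort(cfg)


class TestGwasSumstats:
    def test_null_pvalues_uniform(self, null_cohort):
        geno, ph = null_cohort["genotypes"], null_cohort["phenotypes"]
        pvals = []
        for rep in range(2):
            ss = simulate.simulate_gwas_sumstats(
                geno, ph, np.ones(geno.n, dtype=bool), trait="sbp", seed=20 + rep
            )
            pvals.append(ss["pval"].dropna().to_numpy())
        stat = stats.kstest(np.concatenate(pvals), "uniform")
        assert stat.pvalue > 0.01

    def test_regression_and_analytic_modes_agree(self, null_cohort):
        geno, ph = null_cohort["genotypes"], null_cohort["phenotypes"]
        mask = np.zeros(geno.n, dtype=bool)
        mask[:2000] = True
        reg = simulate.simulate_gwas_sumstats(geno, ph, mask, trait="sbp", seed=1)
        ana = simulate.simulate_gwas_sumstats(
            geno, ph, mask, trait="sbp", seed=2, mode="analytic", n_gwas=int(mask.sum())
        )
        diff = (ana["beta"] - reg["beta"]).dropna()
        se_mean = ana["se"].dropna().mean() / np.sqrt(len(diff))
        assert abs(diff.mean()) < 3 * se_mean

    def test_monomorphic_variant_flagged_not_crashed(self):
        p = np.array([[1 - 1e-12, 0.5]])
        geno = simulate.simulate_genotypes(p, np.ones((300, 1)), ld_block_size=1, seed=16)
        cfg = simulate.CohortConfig(
            n_individuals={"white": 300},
            admixture={"white": (1.0,)},
            ancestries=[simulate.AncestrySpec("EUR")],
            group_residual_sd={"white": 16.0},
            med_use_prob={"white": 0.0},
            m_variants=2,
            m_causal=1,
            heritability_prs=0.0,
            seed=17,
        )
        geno.groups = np.repeat("white", 300)
        ph, _ = simulate.simulate_phenotypes(geno, (np.zeros(2), np.zeros(2)), cfg, seed=18)
        ss = simulate.simulate_gwas_sumstats(geno, ph, np.ones(300, dtype=bool), seed=19)
        assert bool(ss["missing"].iloc[0]) is True
        assert np.isnan(ss["beta"].iloc[0])
        assert not ss["missing"].iloc[1]

    def test_empty_subset_rejected(self, null_cohort):
        geno, ph = null_cohort["genotypes"], null_cohort["phenotypes"]
        with pytest.raises(InputError):
            simulate.simulate_gwas_sumstats(geno, ph, np.zeros(geno.n, dtype=bool))
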