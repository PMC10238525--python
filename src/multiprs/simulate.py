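"""Synthetic multi-ancestry cohort generator.

Generates genotypes, blood-pressure-like phenotypes, kinship and GWAS
summary statistics with the statistical structure the downstream PRS
pipeline assumes:

* K ancestral populations whose allele frequencies diverge from a shared
  ancestral pool under the Balding-Nichols model (Beta draws whose
  variance is controlled by FST);
* admixed individuals with known ancestry proportions, arranged in
  self-identified background groups;
* block LD: within blocks of consecutive variants, haplotype alleles are
  drawn from a Gaussian copula with exchangeable correlation, giving a
  controllable within-block dosage r-squared and exact independence
  across blocks;
* polygenic systolic/diastolic traits with age, age-squared, sex, BMI and
  smoking covariate effects, group-specific residual variances and an
  antihypertensive-treatment effect (-15 mmHg SBP / -10 mmHg DBP in
  treated individuals, which the downstream medication adjustment undoes);
* sib-like relatedness pairs sharing one full haplotype;
* per-population GWAS summary statistics, either by actually running
  covariate-adjusted single-SNP regressions ("regression" mode) or by
  drawing effect estimates around the in-sample marginal effect with the
  analytic standard error ("analytic" mode, emulating a much larger GWAS).

All randomness flows through explicit integer seeds; the same seed and
configuration reproduce the same cohort bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError

__all__ = [
    "AncestrySpec",
    "CohortConfig",
    "GenotypeMatrix",
    "simulate_ancestral_frequencies",
    "simulate_population_frequencies",
    "simulate_genotypes",
    "draw_causal_effects",
    "simulate_phenotypes",
    "simulate_gwas_sumstats",
    "simulate_cohort",
    "grm_kinship",
    "kinship_table",
]

SMOKING_LEVELS = ("never", "former", "current")

# treatment effect of antihypertensive medication on measured BP (mmHg);
# the cohort-prep medication adjustment adds the same constants back
MED_SBP_LOWERING = 15.0
MED_DBP_LOWERING = 10.0


@dataclass(frozen=True)
class AncestrySpec:
    """One ancestral population: divergence and emulated GWAS size."""

    name: str
    fst: float = 0.1
    n_train_gwas: int = 100_000

    def __post_init__(self):
        if not 0.0 < self.fst < 1.0:
            raise ConfigurationError(f"fst must lie in (0,1), got {self.fst}")
        if self.n_train_gwas < 1:
            raise ConfigurationError("n_train_gwas must be >= 1")


def _default_ancestries():
    return [
        AncestrySpec("EUR", fst=0.05, n_train_gwas=500_000),
        AncestrySpec("AFR", fst=0.12, n_train_gwas=100_000),
        AncestrySpec("EAS", fst=0.10, n_train_gwas=140_000),
    ]


def _default_admixture():
    # mean ancestry proportions per self-identified background group
    return {
        "white": (0.96, 0.02, 0.02),
        "black": (0.20, 0.78, 0.02),
        "asian": (0.03, 0.02, 0.95),
    }


@dataclass
class CohortConfig:
    """Configuration of one synthetic cohort.

    ``group_residual_sd`` expresses the residual (non-genetic,
    non-covariate) SD of SBP per background group in mmHg; DBP residual
    SDs are scaled by ``dbp_sd_ratio``.  The defaults put ~25% more
    residual variance in the black group than the white group, mirroring
    the heteroskedasticity the evaluation model has to absorb.
    """

    ancestries: list[AncestrySpec] = field(default_factory=_default_ancestries)
    n_individuals: dict[str, int] = field(
        default_factory=lambda: {"white": 1200, "black": 1000, "asian": 800}
    )
    admixture: dict[str, tuple] = field(default_factory=_default_admixture)
    admixture_concentration: float = 60.0
    m_variants: int = 1000
    m_causal: int = 100
    ld_block_size: int = 10
    ld_rho: float = 0.5
    heritability_prs: float = 0.10
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {
            "age": 0.45,
            "age2": 0.004,
            "sex": -3.0,
            "bmi": 0.8,
            "smoking": 1.5,
        }
    )
    group_residual_sd: dict[str, float] = field(
        default_factory=lambda: {"white": 16.0, "black": 17.9, "asian": 16.0}
    )
    dbp_sd_ratio: float = 0.65
    med_use_prob: dict[str, float] = field(
        default_factory=lambda: {"white": 0.25, "black": 0.35, "asian": 0.25}
    )
    relatedness_pairs: int = 20
    freq_range: tuple = (0.05, 0.95)
    pos_spacing: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.heritability_prs < 1.0:
            raise ConfigurationError("heritability_prs must lie in [0,1)")
        if self.m_causal > self.m_variants:
            raise ConfigurationError("m_causal cannot exceed m_variants")
        for g, sd in self.group_residual_sd.items():
            if sd <= 0:
                raise ConfigurationError(f"residual SD for group {g!r} must be > 0")
        if set(self.n_individuals) - set(self.admixture):
            raise ConfigurationError("every group needs an admixture profile")
        k = len(self.ancestries)
        for g, prof in self.admixture.items():
            if len(prof) != k:
                raise ConfigurationError(
                    f"admixture profile for {g!r} has {len(prof)} entries, expected {k}"
                )
        if not 0 < self.ld_rho < 1:
            raise ConfigurationError("ld_rho must lie in (0,1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ancestries"] = [dataclasses.asdict(a) for a in self.ancestries]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "ancestries" in d:
            d["ancestries"] = [
                a if isinstance(a, AncestrySpec) else AncestrySpec(**a)
                for a in d["ancestries"]
            ]
        for key in ("admixture",):
            if key in d:
                d[key] = {g: tuple(v) for g, v in d[key].items()}
        if "freq_range" in d:
            d["freq_range"] = tuple(d["freq_range"])
        return cls(**d)


@dataclass
class GenotypeMatrix:
    """Dosage matrix plus variant metadata and ancestry proportions.

    ``dosages`` is (n_individuals, m_variants), values in [0, 2] or NaN
    for missing.  ``variants`` carries chrom, pos (1-based),
    other_allele, effect_allele; the effect allele is the counted one.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    ids: np.ndarray
    ancestry_proportions: np.ndarray
    ancestry_names: list[str]
    groups: np.ndarray | None = None

    def __post_init__(self):
        d = self.dosages
        valid = np.isnan(d) | ((d >= 0) & (d <= 2))
        if not valid.all():
            raise InputError("dosages must lie in [0,2] or be NaN")
        q = self.ancestry_proportions
        if q.shape != (d.shape[0], len(self.ancestry_names)):
            raise InputError("ancestry proportion shape mismatch")
        if (q < 0).any() or np.abs(q.sum(axis=1) - 1).max() > 1e-8:
            raise InputError("ancestry proportions must be nonnegative and sum to 1")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Effect-allele frequencies, ignoring missing dosages."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def variant_ids(self) -> pd.Series:
        v = self.variants
        return (
            v["chrom"].astype(str)
            + ":"
            + v["pos"].astype(str)
            + ":"
            + v["other_allele"]
            + ":"
            + v["effect_allele"]
        )


def simulate_ancestral_frequencies(m_variants, freq_range=(0.05, 0.95), seed=0):
    """Draw ancestral-pool allele frequencies uniformly on ``freq_range``."""
    lo, hi = freq_range
    if not (0 < lo <= hi < 1):
        raise ConfigurationError(f"freq_range must satisfy 0 < lo <= hi < 1, got {freq_range}")
    rng = np.random.default_rng(seed)
    return rng.uniform(lo, hi, size=m_variants)


def simulate_population_frequencies(ancestral_freqs, fst, seed=0):
    """Balding-Nichols population frequencies.

    Draws Beta(p(1-F)/F, (1-p)(1-F)/F) per variant, so the expectation is
    the ancestral frequency p and the variance is F p (1-p).
    """
    if not 0.0 < fst < 1.0:
        raise ConfigurationError(f"fst must lie in (0,1), got {fst}")
    p = np.asarray(ancestral_freqs, dtype=float)
    rng = np.random.default_rng(seed)
    scale = (1.0 - fst) / fst
    out = rng.beta(p * scale, (1.0 - p) * scale)
    # keep frequencies strictly inside (0,1): a Beta draw can underflow
    return np.clip(out, 1e-9, 1.0 - 1e-9)


def _make_variant_table(m, pos_spacing=10_000, seed=0):
    rng = np.random.default_rng(seed)
    # sample non-ambiguous allele pairs (no A/T, no C/G) so synthetic
    # variants survive strand-ambiguity filtering by construction
    pairs = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]
    idx = rng.integers(0, len(pairs), size=m)
    swap = rng.random(m) < 0.5
    other = np.array([pairs[i][0] for i in idx], dtype=object)
    eff = np.array([pairs[i][1] for i in idx], dtype=object)
    other2 = np.where(swap, eff, other)
    eff2 = np.where(swap, other, eff)
    return pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, m + 1) * pos_spacing,
            "other_allele": other2,
            "effect_allele": eff2,
        }
    )


def _draw_haplotype(pop_freqs, anc_assign, block_ids, rho, rng):
    """One haplotype per individual: copula-correlated alleles within blocks.

    anc_assign: (n, n_blocks) ancestry index per individual per block.
    Returns int8 (n, m) allele indicators.
    """
    n, n_blocks = anc_assign.shape
    m = len(block_ids)
    shared = rng.standard_normal((n, n_blocks))
    indep = rng.standard_normal((n, m))
    z = np.sqrt(rho) * shared[:, block_ids] + np.sqrt(1.0 - rho) * indep
    u = stats.norm.cdf(z)
    p_used = pop_freqs[anc_assign[:, block_ids], np.arange(m)[None, :]]
    return (u < p_used).astype(np.int8)


def simulate_genotypes(
    pop_freqs,
    ancestry_proportions,
    ld_block_size=10,
    ld_rho=0.5,
    seed=0,
    relatedness_pairs=0,
    variants=None,
    pos_spacing=10_000,
    ancestry_names=None,
    groups=None,
    ids=None,
):
    """Simulate admixed diploid dosages with block LD.

    For each individual, each haplotype and each LD block, an ancestry is
    drawn from the individual's proportions; alleles within the block are
    then drawn from that population's frequencies through an exchangeable
    Gaussian copula with correlation ``ld_rho``.  ``relatedness_pairs``
    consecutive pairs (0,1), (2,3), ... have the second member's first
    haplotype replaced by a copy of the first member's, giving sib-like
    kinship of about 1/4.
    """
    pop_freqs = np.atleast_2d(np.asarray(pop_freqs, dtype=float))
    q = np.atleast_2d(np.asarray(ancestry_proportions, dtype=float))
    k, m = pop_freqs.shape
    n = q.shape[0]
    if q.shape[1] != k:
        raise InputError(
            f"ancestry proportions have {q.shape[1]} columns but {k} populations given"
        )
    if np.abs(q.sum(axis=1) - 1.0).max() > 1e-8:
        raise InputError("ancestry proportion rows must sum to 1")
    if 2 * relatedness_pairs > n:
        raise ConfigurationError("too many relatedness pairs for cohort size")

    rng = np.random.default_rng(seed)
    block_ids = np.arange(m) // max(int(ld_block_size), 1)
    n_blocks = block_ids[-1] + 1 if m else 0

    # ancestry per (individual, haplotype, block) via inverse-CDF on q
    cum = np.cumsum(q, axis=1)
    haps = []
    for _ in range(2):
        u_anc = rng.random((n, n_blocks))
        anc = (u_anc[:, :, None] > cum[:, None, :]).sum(axis=2)
        haps.append(_draw_haplotype(pop_freqs, anc, block_ids, ld_rho, rng))
    h0, h1 = haps

    for pair in range(relatedness_pairs):
        a, b = 2 * pair, 2 * pair + 1
        h0[b] = h0[a]

    dosages = (h0 + h1).astype(float)
    if variants is None:
        variants = _make_variant_table(m, pos_spacing=pos_spacing, seed=seed + 1)
    if ancestry_names is None:
        ancestry_names = [f"POP{i + 1}" for i in range(k)]
    if ids is None:
        ids = np.array([f"I{i:06d}" for i in range(n)])
    return GenotypeMatrix(
        dosages=dosages,
        variants=variants.reset_index(drop=True),
        ids=np.asarray(ids),
        ancestry_proportions=q,
        ancestry_names=list(ancestry_names),
        groups=None if groups is None else np.asarray(groups),
    )


def draw_causal_effects(m_variants, m_causal, seed=0, dbp_corr=0.7):
    """Sparse causal effect vectors for SBP and DBP on shared variants.

    Effects are standard-normal at ``m_causal`` positions chosen uniformly;
    DBP effects share the causal variants with correlation ``dbp_corr``.
    Magnitudes are nominal: phenotype simulation rescales the genetic
    component to hit the configured heritability.
    """
    rng = np.random.default_rng(seed)
    idx = rng.choice(m_variants, size=m_causal, replace=False)
    beta_sbp = np.zeros(m_variants)
    beta_dbp = np.zeros(m_variants)
    z1 = rng.standard_normal(m_causal)
    z2 = rng.standard_normal(m_causal)
    beta_sbp[idx] = z1
    beta_dbp[idx] = dbp_corr * z1 + np.sqrt(1 - dbp_corr**2) * z2
    return beta_sbp, beta_dbp


def _scaled_genetic_value(dosages, beta, h2, mean_resid_var):
    g = dosages @ beta
    vg = g.var()
    if h2 > 0 and vg <= 0:
        raise ConfigurationError(
            "heritability_prs > 0 requested but causal effects give zero genetic variance"
        )
    if h2 == 0 or vg == 0:
        return np.zeros_like(g), np.zeros_like(beta)
    target = h2 / (1.0 - h2) * mean_resid_var
    scale = np.sqrt(target / vg)
    return (g - g.mean()) * scale, beta * scale


def simulate_phenotypes(genotypes, causal_effects, config, seed=0, groups=None):
    """Simulate SBP/DBP, covariates and medication use.

    Returns ``(pheno, truth)``: a phenotype/covariate table (id, group,
    age, sex, bmi, smoking, med_use, sbp, dbp) and a truth dict with the
    rescaled per-variant effects and per-individual genetic values used,
    for parameter-recovery tests.  Measured BP in medicated individuals
    is lowered by the treatment effect (15/10 mmHg).
    """
    beta_sbp, beta_dbp = causal_effects
    m = genotypes.m
    if len(beta_sbp) != m or len(beta_dbp) != m:
        raise InputError("causal effect vectors must match the variant count")
    if groups is None:
        groups = genotypes.groups
    if groups is None:
        raise InputError("group labels required (pass groups= or set genotypes.groups)")
    groups = np.asarray(groups)
    n = genotypes.n
    rng = np.random.default_rng(seed)

    group_sd = np.array([config.group_residual_sd[g] for g in groups])
    mean_resid_var = float(np.mean(group_sd**2))
    h2 = config.heritability_prs
    X = np.nan_to_num(genotypes.dosages)
    g_sbp, b_sbp_scaled = _scaled_genetic_value(X, beta_sbp, h2, mean_resid_var)
    g_dbp, b_dbp_scaled = _scaled_genetic_value(
        X, beta_dbp, h2, mean_resid_var * config.dbp_sd_ratio**2
    )

    age = rng.uniform(20, 80, n)
    sex = rng.integers(0, 2, n)  # 1 = male
    bmi = np.clip(rng.normal(28, 5, n), 15, None)
    smoking = rng.choice(SMOKING_LEVELS, size=n, p=(0.5, 0.3, 0.2))
    smoke_num = np.select(
        [smoking == "never", smoking == "former", smoking == "current"], [0.0, 1.0, 2.0]
    )
    ce = config.covariate_effects
    cov_part = (
        ce["age"] * (age - 50.0)
        + ce["age2"] * ((age - 50.0) ** 2 - np.mean((age - 50.0) ** 2))
        + ce["sex"] * sex
        + ce["bmi"] * (bmi - 28.0)
        + ce["smoking"] * smoke_num
    )

    eps_sbp = rng.standard_normal(n) * group_sd
    eps_dbp = rng.standard_normal(n) * group_sd * config.dbp_sd_ratio
    sbp_true = 125.0 + cov_part + g_sbp + eps_sbp
    dbp_true = 75.0 + 0.5 * cov_part + g_dbp + eps_dbp

    med_p = np.array([config.med_use_prob[g] for g in groups])
    med_use = rng.random(n) < med_p
    sbp = sbp_true - MED_SBP_LOWERING * med_use
    dbp = dbp_true - MED_DBP_LOWERING * med_use
    # keep the systolic/diastolic ordering physiological
    bad = dbp >= sbp
    dbp[bad] = sbp[bad] - 5.0

    pheno = pd.DataFrame(
        {
            "id": genotypes.ids,
            "group": groups,
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "smoking": smoking,
            "med_use": med_use.astype(int),
            "sbp": sbp,
            "dbp": dbp,
        }
    )
    truth = {
        "beta_sbp": b_sbp_scaled,
        "beta_dbp": b_dbp_scaled,
        "g_sbp": g_sbp,
        "g_dbp": g_dbp,
        "heritability_prs": h2,
        "group_residual_sd": dict(config.group_residual_sd),
    }
    return pheno, truth


def _covariate_design(pheno):
    smoke_num = np.select(
        [pheno["smoking"] == "never", pheno["smoking"] == "former"],
        [0.0, 1.0],
        default=2.0,
    )
    age = pheno["age"].to_numpy(float)
    return np.column_stack(
        [
            np.ones(len(pheno)),
            age,
            age**2,
            pheno["sex"].to_numpy(float),
            pheno["bmi"].to_numpy(float),
            smoke_num,
        ]
    )


def simulate_gwas_sumstats(
    genotypes,
    phenotypes,
    population_subset,
    trait="sbp",
    seed=0,
    mode="regression",
    n_gwas=None,
):
    """Per-variant GWAS summary statistics on a cohort subset.

    mode="regression": single-SNP regressions of the covariate-adjusted
    trait on dosage; reported n is the subset size.  mode="analytic":
    effect estimates are drawn around the subset's in-sample marginal
    effect with SE = sd_resid / sqrt(2 n p (1-p)) at n = ``n_gwas``,
    emulating a GWAS far larger than the simulated cohort.
    Monomorphic variants get NaN beta/se/p and missing=True.
    """
    mask = np.asarray(population_subset)
    if mask.dtype != bool:
        mask = np.isin(genotypes.ids, mask)
    if mask.sum() == 0:
        raise InputError("population subset is empty")
    X = np.nan_to_num(genotypes.dosages[mask])
    ph = phenotypes.loc[mask].reset_index(drop=True)
    y = ph[trait].to_numpy(float)
    n_sub = len(y)

    C = _covariate_design(ph)
    # residualize trait on covariates once; per-variant simple regression after
    coef, *_ = np.linalg.lstsq(C, y, rcond=None)
    r = y - C @ coef

    p_hat = X.mean(axis=0) / 2.0
    xc = X - X.mean(axis=0)
    var_x = (xc**2).mean(axis=0)
    mono = var_x <= 0

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (xc * r[:, None]).mean(axis=0) / var_x
    rng = np.random.default_rng(seed)

    if mode == "regression":
        resid_var = np.maximum(
            r @ r / n_sub - beta**2 * var_x, 1e-12
        )  # per-variant residual variance of r on x
        se = np.sqrt(resid_var / (n_sub * var_x))
        beta_hat = beta
        n_out = n_sub
    elif mode == "analytic":
        if n_gwas is None:
            raise ConfigurationError("analytic mode requires n_gwas")
        sd_resid = float(r.std())
        with np.errstate(divide="ignore", invalid="ignore"):
            se = sd_resid / np.sqrt(2.0 * n_gwas * p_hat * (1.0 - p_hat))
        beta_hat = beta + rng.standard_normal(genotypes.m) * np.where(mono, 0.0, se)
        n_out = int(n_gwas)
    else:
        raise ConfigurationError(f"unknown summary-statistic mode {mode!r}")

    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta_hat / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)

    out = genotypes.variants.copy()
    out["beta"] = np.where(mono, np.nan, beta_hat)
    out["se"] = np.where(mono, np.nan, se)
    out["pval"] = np.where(mono, np.nan, pval)
    out["eaf"] = p_hat
    out["n"] = n_out
    out["missing"] = mono
    return out


def grm_kinship(genotypes, min_maf=0.01, groups=None):
    """Naive allele-frequency-standardized GRM, returned as kinship (GRM/2).

    A fixture-grade estimator: standardize dosages by sqrt(2 p (1-p)) at
    the sample frequency and average cross-products over variants with
    MAF above ``min_maf``.  When ``groups`` labels are given (default:
    the genotypes' own group labels), centering and scaling use
    group-specific frequencies, which removes the spurious within-group
    relatedness that population structure induces in an unadjusted GRM
    (a crude stand-in for ancestry-adjusted kinship estimation).
    """
    X = np.nan_to_num(genotypes.dosages)
    if groups is None:
        groups = genotypes.groups
    p = X.mean(axis=0) / 2.0
    keep = (p >= min_maf) & (p <= 1 - min_maf)
    if keep.sum() == 0:
        raise InputError("no polymorphic variants for the GRM")
    Xk = X[:, keep]
    if groups is not None:
        groups = np.asarray(groups)
        Xs = np.empty_like(Xk)
        for g in np.unique(groups):
            rows = groups == g
            pg = np.clip(Xk[rows].mean(axis=0) / 2.0, 1e-3, 1 - 1e-3)
            Xs[rows] = (Xk[rows] - 2 * pg) / np.sqrt(2 * pg * (1 - pg))
    else:
        pk = p[keep]
        Xs = (Xk - 2 * pk) / np.sqrt(2 * pk * (1 - pk))
    grm = Xs @ Xs.T / keep.sum()
    return grm / 2.0


def kinship_table(kin, ids, min_kinship=2.0 ** -3.5):
    """Sparse triplet table (id1, id2, kinship) of off-diagonal pairs above a floor.

    The default floor is the third-degree cutoff 2^-3.5: on a desk-scale
    variant panel, estimated kinship below that is dominated by noise,
    so the sparse fixture retains close relatives only.
    """
    iu = np.triu_indices_from(kin, k=1)
    vals = kin[iu]
    sel = vals > min_kinship
    ids = np.asarray(ids)
    return pd.DataFrame(
        {"id1": ids[iu[0][sel]], "id2": ids[iu[1][sel]], "kinship": vals[sel]}
    )


def simulate_cohort(config: CohortConfig):
    """End-to-end cohort draw from a :class:`CohortConfig`.

    Returns a dict with keys genotypes, phenotypes, truth, kinship (dense
    matrix), kinship_table, causal_effects, pop_freqs, ancestral_freqs.
    """
    rng_seed = config.seed
    anc = config.ancestries
    k = len(anc)
    p0 = simulate_ancestral_frequencies(
        config.m_variants, config.freq_range, seed=rng_seed
    )
    pop_freqs = np.vstack(
        [
            simulate_population_frequencies(p0, anc[i].fst, seed=rng_seed + 1 + i)
            for i in range(k)
        ]
    )
    groups = np.concatenate(
        [np.repeat(g, n) for g, n in config.n_individuals.items()]
    )
    n = len(groups)
    rng = np.random.default_rng(rng_seed + 100)
    q = np.vstack(
        [
            rng.dirichlet(
                np.maximum(np.array(config.admixture[g]) * config.admixture_concentration, 1e-3)
            )
            for g in groups
        ]
    )
    genotypes = simulate_genotypes(
        pop_freqs,
        q,
        ld_block_size=config.ld_block_size,
        ld_rho=config.ld_rho,
        seed=rng_seed + 200,
        relatedness_pairs=config.relatedness_pairs,
        pos_spacing=config.pos_spacing,
        ancestry_names=[a.name for a in anc],
        groups=groups,
    )
    causal = draw_causal_effects(config.m_variants, config.m_causal, seed=rng_seed + 300)
    pheno, truth = simulate_phenotypes(genotypes, causal, config, seed=rng_seed + 400)
    kin = grm_kinship(genotypes)
    return {
        "genotypes": genotypes,
        "phenotypes": pheno,
        "truth": truth,
        "kinship": kin,
        "kinship_table": kinship_table(kin, genotypes.ids),
        "causal_effects": causal,
        "pop_freqs": pop_freqs,
        "ancestral_freqs": p0,
    }
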