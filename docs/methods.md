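# Methods

This note records the models implemented in `multiprs`, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate,
and the numerical choices made where the design was genuinely open. No
empirical figure is quoted here that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic cohorts

The generator (`multiprs.simulate`) produces the statistical structure
the downstream pipeline assumes, at desk scale.

**Allele frequencies.** An ancestral pool draws frequencies uniformly on
(0.05, 0.95); each of K ancestral populations diverges from it by a
Balding–Nichols draw, Beta(p(1−F)/F, (1−p)(1−F)/F), whose mean is the
ancestral frequency p and whose variance is F·p(1−p). F (FST) is the
single divergence knob; defaults (0.05 EUR-like, 0.12 AFR-like, 0.10
EAS-like) give realistic continental-scale differentiation. K defaults
to 3 — enough to exercise every multi-ancestry branch without the cost
of a seven-way panel.

**Genotypes and LD.** Individuals carry ancestry proportions drawn from
group-specific Dirichlet distributions (default groups: a mostly-EUR
"white" group, an admixed ~20/80 EUR/AFR "black" group, a mostly-EAS
"asian" group). Per haplotype and per LD block, an ancestry is drawn
from the individual's proportions and alleles are generated from that
population's frequencies through an exchangeable Gaussian copula with
correlation ρ (default 0.5) inside blocks of `ld_block_size` consecutive
variants (default 10). This gives exactly independent blocks — so
brute-force r² oracles are clean — and controllable within-block r²; it
is not a recombination-map LD model, which clumping does not need.
Sib-like pairs are injected by copying one haplotype between two
individuals, giving kinship ≈ 1/4.

**Phenotypes.** SBP = 125 + covariate effects (age, centered age², sex,
BMI, smoking as a 0/1/2 trend) + genetic value + group-specific Gaussian
noise; DBP analogously around 75 with shared causal variants (effect
correlation 0.7) and a 0.65 residual-SD ratio. The genetic value from
`m_causal` variants is rescaled so that its variance is
h²/(1−h²) × (mean group residual variance), making the configured
`heritability_prs` the covariate-adjusted variance fraction the true
score explains. Default group residual SDs (16, 17.9, 16 mmHg) encode
the ~25% higher residual variance observed in Black relative to White
participants in the cohorts this design emulates. Medication use
(group-specific Bernoulli) *lowers* measured BP by 15/10 mmHg, so the
downstream +15/+10 adjustment recovers the underlying trait — the two
constants are deliberately the same.

**Kinship fixture.** Kinship is normally an input file; for fixtures a
naive allele-frequency-standardized GRM/2 is provided, with centering
and scaling per background group to remove the spurious within-group
relatedness that population structure induces (ancestry-adjusted
estimation proper is out of scope). On a desk-scale panel the
estimator's noise SD is ≈ 1/(2√m); the sparse triplet export therefore
keeps only pairs above the third-degree cutoff 2⁻³·⁵, which separates
the injected sib pairs (~0.25) from noise once m ≳ 1000.

**GWAS summary statistics.** Regression mode runs covariate-adjusted
single-SNP regressions on a cohort subset and is the ground truth.
Analytic mode draws β̂ ~ Normal(in-sample marginal β, se) with
se = sd_resid/√(2·n·p(1−p)) at an emulated sample size `n_train_gwas`
(defaults 500k/100k/140k per ancestry, mimicking the order-of-magnitude
imbalance between European and other discovery GWAS); the two modes are
cross-checked against each other in the tests. Monomorphic variants are
emitted with a missing flag rather than dropped silently.

**What the generator does not emulate:** realistic LD maps and allele
ages, genotyping/imputation error, X chromosome, local-ancestry tracts,
medication selection-on-phenotype, longitudinal BP. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative model, not performance on real cohorts.

## Harmonization

Variants are matched to the panel by (chrom, pos, unordered allele pair)
on one genome build (build liftover is out of scope; positions are
1-based as in VCF). QC removes variants with MAF < 0.01 in the panel or
in the GWAS (GWAS-side MAF from min(eaf, 1−eaf); records without eaf
pass unless strict mode) and panel missingness ≥ 1%. Strand-ambiguous
pairs (A/T, C/G) are always removed: a frequency-based rescue at extreme
MAF was considered and rejected, because a silent strand error is worse
than a dropped variant, and for the same reason reverse-strand
complementing of non-ambiguous alleles is off by default. Swapped
codings are flipped (β negated, eaf complemented, `flipped` flag set).
Every report partitions its input exactly
(input = retained + removals + unmatched), and harmonization is
idempotent.

## PRS construction

Clumping is greedy with PRSice semantics: candidates with p ≤ threshold
are ordered by ascending p (ties broken by chrom, pos — deterministic
where tool behavior is unspecified); the best remaining variant becomes
an index SNP and removes unselected variants on the same chromosome
within `window_kb` (|Δpos| ≤ 1000 kb by default) whose squared dosage
correlation in the designated reference panel exceeds `r2_max` (0.1).
Removed variants can never seed a later clump. Monomorphic panel
variants have undefined r², treated as 0. The reference panel
(multi-ancestry vs background-specific) is a configuration axis, and r²
is computed on dosages. The implementation is verified exactly against
a literal re-scanning oracle on random instances.

Scoring is additive with missing dosages imputed as 2×EAF by default
(per-sample renormalization available). Standardization stores the
reference cohort's mean/SD; external cohorts reuse those constants, so
group differences in mean PRS — driven by Σ_v w_v·2Δp_v allele-frequency
differences, an identity the tests assert — remain visible on the
common scale. Weight tables round-trip to 3-column PLINK `--score`
files.

## Combination

Weights come from a single joint OLS of the training phenotype on
[intercept, covariates, all components], not marginal fits; the
covariate list is configurable because it legitimately differs between
cohorts. Negative weights pass through unmodified. Scope `per_group`
trains within the background group being evaluated (primary);
`all` uses every training row (secondary) — neither is privileged.
Rank-deficient designs raise a collinearity error naming the offending
columns (identified from the SVD null space). `scale` equalizes SDs
across datasets; `scale_match` maps source to target through the
interpolated empirical CDF — strictly monotone on the source range,
hence rank-preserving, and deterministic.

## Cohort preparation

Medication adjustment adds exactly +15 mmHg (SBP) / +10 mmHg (DBP) for
medicated records and stamps a provenance flag so it cannot be applied
twice; missing flags are treated as unmedicated under the default
lenient policy (logged) or rejected under strict. Age bands are ≤40,
(40,60], >60 — age 40 falls in the first band, resolving an ambiguity
between two plausible conventions in favor of the stated "≤40"; obesity
is BMI ≥ 30, inclusive. Unrelated selection drops, repeatedly, the
individual with the most kinship pairs above 2⁻⁴·⁵ ≈ 0.0442 (ties: the
lexicographically larger id), a deterministic, edge-order-invariant
approximation of partition heuristics used in mixed-model software; the
exact partition algorithm of those packages is not reproduced.

## Association and PVE

Without kinship, group-heteroskedastic models are fit by iterated FGLS
(WLS with current group variances; re-estimate variances from residuals;
stop at relative change < 1e-8 or 50 iterations), and a
`fixed_variances` mode gives closed-form WLS for oracle checks. With
kinship, the two-variance-component model y = Xb + g + e,
g ~ (0, σ²_g·2K), is fit by profiling the likelihood over
φ = σ²_g/σ²_total via the eigendecomposition of 2K (coarse log-spaced
grid, golden-section refinement, explicit boundary check at φ = 0).
When variance groups and kinship are both requested, rows are first
whitened by the FGLS group SDs and the polygenic component is profiled
on the whitened data with homogeneous residuals — how heterogeneous
variances and the random effect should interact is not fully
determined, and this two-stage choice keeps each piece testable. Wald
tests use the normal reference.

PVE uses the unrelated subset and, by default, σ̂² = RSS/n in both
models, which makes PVE exactly the partial R² of the PRS given the
covariates (an identity the tests assert to 1e-10) and invariant to any
affine transform of the PRS. With variance groups, a `pooled` mode runs
FGLS per model and pools group variances by degrees of freedom; under
homoskedasticity it agrees with the default. Negative PVE is reported
as-is, never truncated. The bootstrap resamples individuals within the
fixed unrelated subset (unrelated selection is not redone per replicate
— deterministic and far cheaper, at the cost of ignoring selection
variability), 1000 replicates by default, CI from the 2.5/97.5
percentiles; singular resampled designs are redrawn up to 10 times.
Empirical coverage of the 95% interval is checked by simulation in the
acceptance suite. Strata below n = 50 are skipped with a warning, and
covariates constant within a stratum (e.g. sex inside a sex stratum)
are dropped from that stratum's design. Whether group intercepts are
retained inside strata defined by the same grouping is configurable via
the `group_col` argument. AUC is the midrank Mann–Whitney statistic.

## Ancestry diagnostics

Ancestry-specific frequencies solve min_p ‖dosage − 2Qp‖² with
p_k ∈ [0,1] per variant (BVLS), using global admixture proportions —
a deliberate simplification of local-ancestry-aware estimators, unbiased
when the global-admixture model holds and exact in the single-ancestry
limit. Identifiability requires non-collinear proportion columns, and
the attainable precision is set by the admixture design: with
near-pure individuals present (Beta(0.5,0.5)-like proportions), n = 2000
recovers frequencies within ±0.03 for ≥95% of variants, the regime the
acceptance suite checks. Dropping a low-sample ancestry renormalizes
rows whose dropped fraction is ≤ 0.05 (the "small fraction" cap is
otherwise unquantified; 5% is this package's choice) and flags the rest
excluded. The effect-size profile bins clumped, sub-significant
(p < 0.01) variants by deciles of ancestry-specific frequency — decile
binning is this package's choice where no binning is prescribed — and
summarizes median/IQR of |β| per bin; empty bins are omitted, not
zeroed.

## Pipeline and problem sizes

The end-to-end driver simulates three disjoint cohorts from one shared
variant space and causal architecture — a GWAS cohort (summary
statistics in analytic mode at the emulated discovery sizes), a training
cohort for combination weights, and an evaluation cohort that is also
the standardization reference and LD panel — then runs every stage and
writes a run report with seeds, per-stage counts and SHA-256 hashes of
all outputs; reruns with the same configuration are byte-identical. The
bundled demo uses two ancestries, 2000 variants and ~3000 individuals
per cohort with 200 bootstrap replicates; the acceptance script uses
three ancestries, 1000 variants, n = 10000 for heritability recovery and
100×300-replicate runs for bootstrap coverage. These sizes were chosen
as the smallest at which the nominal statistical behavior (coverage,
recovery tolerances) is expected to hold; all scale linearly if raised.

## Known limitations

Single-build, SNP-only harmonization (no indels, no multi-allelics, no
liftover); no Bayesian shrinkage weight training (external weight tables
are consumed, not produced); no meta-analysis of summary statistics on
different scales; no incident/survival outcomes; global-ancestry (not
local-ancestry) frequency estimation; the kinship+heteroskedasticity
interaction is approximate as described above; and the synthetic
cohorts' simplifications listed in the first section bound what the
green test suite implies about real data.
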