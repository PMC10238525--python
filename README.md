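# multiprs

Construction, combination and evaluation of polygenic risk scores (PRSs)
for blood-pressure traits across population groups.

PRSs built from a single GWAS transfer poorly across ancestries: effect
sizes and allele frequencies differ, discovery sample sizes are
unbalanced, and residual trait variance differs between population
groups. `multiprs` implements the full analysis chain used to study this
problem — harmonizing GWAS summary statistics to a target genotype
panel, building clump-and-threshold PRSs against an LD reference,
combining component PRSs from several GWAS into simple and
regression-weighted sums, and evaluating each score's percent variance
explained (PVE) with percentile-bootstrap confidence intervals, in the
whole cohort and within strata of background group, age, sex, BMI and
antihypertensive-medication use. Because the individual-level cohorts
such analyses run on are access-restricted, the package ships a
first-class synthetic-cohort generator (Balding–Nichols allele-frequency
divergence, block LD, admixture, polygenic SBP/DBP with group-specific
residual variances, relatedness, per-population GWAS summary statistics)
so every stage is testable end to end.

It is intended for statistical geneticists who want a transparent,
tested, scriptable implementation of this pipeline — either as a Python
library or through the thin `multiprs` command-line wrapper.

## The statistics in brief

* **Clump-and-threshold PRS.** Greedy LD clumping (index variants chosen
  by ascending p; neighbors within 1000 kb with dosage r² > 0.1 removed)
  at p-value thresholds {5×10⁻⁸, 1×10⁻⁵, 1×10⁻²}; additive scoring
  PRS_j = Σ_v w_v · dosage_jv; each PRS standardized to mean 0 / SD 1 in
  a reference cohort. Externally trained per-SNP weight tables (e.g.
  from Bayesian shrinkage methods) are consumed through the same
  `WeightTable` format, skipping clumping.
* **Multi-PRS combination.** Simple sum PRS₁+…+PRS_k of standardized
  components, and the weighted sum w₁PRS₁+…+w_kPRS_k with weights taken
  as the component coefficients of one joint linear regression fit in an
  independent training cohort (optionally restricted to the background
  group being evaluated). Cross-dataset distribution shift can be
  addressed by SD rescaling or monotone empirical-quantile matching.
* **Evaluation.** Association models with group-specific intercepts,
  heterogeneous residual variances (FGLS), and an optional polygenic
  random effect with covariance σ²_g·2K for kinship K; effects reported
  in mmHg per reference-cohort SD with a 1-df Wald test. Performance is

      PVE = (1 − σ̂²_prs / σ̂²_null) × 100 %,

  the residual-variance reduction from adding the PRS to the covariate
  model, computed on an unrelated subset (kinship cutoff 2⁻⁴·⁵ ≈ 4.4%)
  with a 1000-replicate percentile bootstrap CI. Medicated individuals'
  SBP/DBP are adjusted by +15/+10 mmHg before analysis. Prevalent
  binary outcomes are assessed by rank-based (Mann–Whitney) AUC.
* **Population-structure diagnostics.** Ancestry-specific allele
  frequencies estimated per variant by box-constrained least squares on
  global admixture proportions (E[dosage] = 2Σ_k q_k p_k), ≥80%-ancestry
  group assignment, and the |β|-versus-ancestry-specific-frequency
  decile profile.

## Worked example

`examples/` contains one short script per capability. The combination
example (`examples/04_combine_prs.py`) builds four component PRSs of
decreasing quality from a shared genetic signal, trains combination
weights in one half of the cohort and evaluates held-out PVE in the
other:

```
trained weights: {'prs1': 0.345, 'prs2': 0.299, 'prs3': 0.187, 'prs4': 0.086}
held-out PVE  best single: 16.38%
held-out PVE   simple sum: 23.02%
held-out PVE weighted sum: 25.27%
```

The trained weights track component quality, and the weighted sum beats
both the best single component and the unweighted sum out of sample —
the central empirical claim the evaluation machinery is built to
measure. The end-to-end demo (`examples/07_full_pipeline.py`, or
`multiprs run --config examples/demo_config.yaml --out run/`) chains
simulate → harmonize → clump → score → combine → prep → evaluate →
diagnostics, writes every intermediate file with a SHA-256 hash into a
run report, and prints the overall evaluation table (PVE with bootstrap
CIs per PRS).

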