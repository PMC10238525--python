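# Downsized end-to-end demo (two ancestries, ~2000 variants, n=3000 per cohort draw).
# Defaults not set here mirror the standard analysis parameters:
# clump r^2 = 0.1, window 1000 kb, thresholds {5e-8, 1e-5, 1e-2},
# kinship cutoff 2^-4.5, ancestry cutoff 0.8, +15/+10 mmHg medication adjustment.
seed: 17
cohort:
  ancestries:
    - {name: EUR, fst: 0.05, n_train_gwas: 400000}
    - {name: AFR, fst: 0.12, n_train_gwas: 100000}
  n_individuals: {white: 1700, black: 1300}
  admixture:
    white: [0.95, 0.05]
    black: [0.20, 0.80]
  group_residual_sd: {white: 16.0, black: 17.9}
  med_use_prob: {white: 0.25, black: 0.35}
  m_variants: 2000
  m_causal: 150
  relatedness_pairs: 15
n_boot: 200
combination_scope: per_group
strata: [all, group, age_band, sex_label, obese, med_stratum]
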