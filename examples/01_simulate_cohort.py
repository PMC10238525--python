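"""Simulate a small multi-ancestry cohort and inspect its structure.

Draws three background groups with admixed ancestry, block-LD genotypes,
polygenic SBP/DBP and a GRM-based kinship fixture, then prints the
group-wise trait summaries and the kinship of the injected sib-like pairs.
"""

import numpy as np

from multiprs import simulate

cfg = simulate.CohortConfig(
    n_individuals={"white": 500, "black": 400, "asian": 300},
    m_variants=600,
    m_causal=80,
    heritability_prs=0.10,
    relatedness_pairs=10,
    seed=42,
)
res = simulate.simulate_cohort(cfg)
geno, pheno = res["genotypes"], res["phenotypes"]

print(f"cohort: n={geno.n} individuals, m={geno.m} variants, "
      f"K={len(geno.ancestry_names)} ancestries {geno.ancestry_names}")
print("\nper-group SBP (mean / SD, mmHg) — the residual SD is configured ~12% higher "
      "in the black group:")
print(pheno.groupby("group")["sbp"].agg(["mean", "std"]).round(1))

kin = res["kinship"]
sibs = [kin[2 * i, 2 * i + 1] for i in range(10)]
print(f"\ninjected sib-like pairs: estimated kinship {np.round(np.mean(sibs), 3)} on average "
      f"(expected ~0.25, i.e. one shared haplotype)")
print(f"sparse kinship table keeps {len(res['kinship_table'])} close pairs "
      f"(floor 2^-3.5 ~= {2**-3.5:.3f})")
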