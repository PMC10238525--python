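"""End-to-end driver: simulate -> harmonize -> clump -> score -> combine -> evaluate.

Emulates the full PRS study design on synthetic data: three disjoint
cohorts are drawn from the same ancestral frequencies and causal
architecture — a GWAS cohort (whose per-group summary statistics emulate
large discovery GWAS through the analytic noise mode), a training cohort
(for multi-PRS combination weights) and an evaluation cohort (the
reference for PRS standardization and the target of all association
analyses).  Every stage writes its outputs under the run directory and
the run report records seeds, row counts and SHA-256 content hashes, so
a rerun with the same configuration reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestry as anc_mod
from . import cohort as cohort_mod
from . import combine as combine_mod
from . import construct, evaluate, io, simulate, sumstats
from .errors import ConfigurationError

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Validated end-to-end run configuration; defaults mirror the
    standard analysis parameters (r^2=0.1, 1000 kb, thresholds
    {5e-8, 1e-5, 1e-2}, kinship cutoff 2^-4.5, ancestry cutoff 0.8,
    +15/+10 mmHg medication adjustment)."""

    seed: int = None  # type: ignore[assignment]
    cohort: dict = field(default_factory=dict)
    n_training: dict | None = None
    r2_max: float = 0.1
    window_kb: float = 1000.0
    p_thresholds: tuple = construct.DEFAULT_P_THRESHOLDS
    component_threshold: float = 1e-2
    combination_scope: str = "per_group"
    strata: tuple = ("all", "group", "age_band", "sex_label", "obese", "med_stratum")
    n_boot: int = 1000
    kinship_threshold: float = cohort_mod.KINSHIP_THRESHOLD
    ancestry_cutoff: float = 0.8
    min_stratum_n: int = 50
    write_genotypes: bool = False

    def __post_init__(self):
        if self.seed is None:
            raise ConfigurationError("config must set an explicit seed")
        if self.n_boot < 0:
            raise ConfigurationError("n_boot must be >= 0")
        self.p_thresholds = tuple(float(p) for p in self.p_thresholds)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _simulate_three_cohorts(cfg: RunConfig):
    base = simulate.CohortConfig.from_dict({**cfg.cohort, "seed": cfg.seed})
    p0 = simulate.simulate_ancestral_frequencies(base.m_variants, base.freq_range, seed=cfg.seed)
    pop_freqs = np.vstack(
        [
            simulate.simulate_population_frequencies(p0, a.fst, seed=cfg.seed + 1 + i)
            for i, a in enumerate(base.ancestries)
        ]
    )
    causal = simulate.draw_causal_effects(base.m_variants, base.m_causal, seed=cfg.seed + 7)
    # one shared variant table: all cohorts live on the same variant space
    variants = simulate._make_variant_table(
        base.m_variants, pos_spacing=base.pos_spacing, seed=cfg.seed + 8
    )

    def draw(name, n_per_group, seed, relpairs):
        groups = np.concatenate([np.repeat(g, n) for g, n in n_per_group.items()])
        rng = np.random.default_rng(seed)
        q = np.vstack(
            [
                rng.dirichlet(np.array(base.admixture[g]) * base.admixture_concentration)
                for g in groups
            ]
        )
        geno = simulate.simulate_genotypes(
            pop_freqs,
            q,
            ld_block_size=base.ld_block_size,
            ld_rho=base.ld_rho,
            seed=seed + 1,
            relatedness_pairs=relpairs,
            pos_spacing=base.pos_spacing,
            variants=variants,
            ancestry_names=[a.name for a in base.ancestries],
            groups=groups,
            ids=np.array([f"{name}{i:06d}" for i in range(len(groups))]),
        )
        pheno, truth = simulate.simulate_phenotypes(geno, causal, base, seed=seed + 2)
        return geno, pheno, truth

    n_train = cfg.n_training or {g: max(n // 2, 50) for g, n in base.n_individuals.items()}
    gwas = draw("G", base.n_individuals, cfg.seed + 1000, 0)
    train = draw("T", n_train, cfg.seed + 2000, 0)
    ev = draw("E", base.n_individuals, cfg.seed + 3000, base.relatedness_pairs)
    return base, pop_freqs, causal, gwas, train, ev


def run_pipeline(config: RunConfig, out_dir):
    """Run every stage; returns the report dict (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {"config": dataclasses.asdict(config), "stages": {}, "files": {}}
    written = {}

    def _write(name, writer, *args):
        path = out / name
        writer(*args, path)
        written[name] = path

    t_all = time.time()

    def stage(name):
        report["stages"][name] = {"t_start": round(time.time() - t_all, 3)}
        return time.time()

    # ---- simulate ------------------------------------------------------
    t = stage("simulate")
    base, pop_freqs, causal, (g_geno, g_pheno, _), (t_geno, t_pheno, _), (e_geno, e_pheno, e_truth) = (
        _simulate_three_cohorts(config)
    )
    kin = simulate.grm_kinship(e_geno)
    kin_table = simulate.kinship_table(kin, e_geno.ids)
    _write("phenotypes.tsv", io.write_pheno_tsv, e_pheno)
    _write("kinship.tsv", io.write_kinship_tsv, kin_table)
    _write("ancestry_proportions.tsv", io.write_proportions_tsv, e_geno)
    if config.write_genotypes:
        _write("genotypes.tsv", io.write_dosage_tsv, e_geno)
        _write("genotypes.vcf", io.write_vcf, e_geno)
    io.write_truth_json(
        {"heritability_prs": e_truth["heritability_prs"], "beta_sbp": e_truth["beta_sbp"]},
        out / "truth.json",
    )
    written["truth.json"] = out / "truth.json"
    report["stages"]["simulate"].update(
        n_eval=int(e_geno.n), n_gwas_cohort=int(g_geno.n), n_training=int(t_geno.n),
        m_variants=int(e_geno.m), seconds=round(time.time() - t, 2),
    )

    # per-group GWAS summary statistics (analytic mode, emulated sizes)
    t = stage("gwas_sumstats")
    anc_by_group = {
        g: int(np.argmax(base.admixture[g])) for g in base.n_individuals
    }
    raw_sumstats = {}
    for trait in ("sbp", "dbp"):
        for grp in base.n_individuals:
            spec = base.ancestries[anc_by_group[grp]]
            ss = simulate.simulate_gwas_sumstats(
                g_geno,
                g_pheno,
                np.asarray(g_geno.groups == grp),
                trait=trait,
                seed=config.seed + 5000 + zlib_crc(f"{trait}:{grp}"),
                mode="analytic",
                n_gwas=spec.n_train_gwas,
            )
            raw_sumstats[(trait, grp)] = ss.dropna(subset=["beta"]).reset_index(drop=True)
            io.write_sumstats_tsv(
                raw_sumstats[(trait, grp)], out / f"sumstats_{trait}_{grp}.tsv"
            )
            written[f"sumstats_{trait}_{grp}.tsv"] = out / f"sumstats_{trait}_{grp}.tsv"
    report["stages"]["gwas_sumstats"].update(
        n_gwas=len(raw_sumstats), seconds=round(time.time() - t, 2)
    )

    # ---- harmonize + QC ------------------------------------------------
    t = stage("harmonize")
    panel = sumstats.panel_variants(e_geno)
    harmonized = {}
    harm_counts = {}
    for key, ss in raw_sumstats.items():
        qc, rep1 = sumstats.qc_filter(ss, panel)
        harm, rep2 = sumstats.harmonize_alleles(qc, panel)
        harmonized[key] = harm
        harm_counts["%s_%s" % key] = {"qc": rep1.to_dict(), "harmonize": rep2.to_dict()}
    report["stages"]["harmonize"].update(counts=harm_counts, seconds=round(time.time() - t, 2))

    # ---- clump + threshold + score + standardize -----------------------
    t = stage("construct")
    components_eval = {"sbp": {}, "dbp": {}}
    components_train = {"sbp": {}, "dbp": {}}
    ref_constants = {}
    n_index = {}
    for (trait, grp), harm in harmonized.items():
        for p_thr in config.p_thresholds:
            params = construct.ClumpParams(config.r2_max, config.window_kb, p_thr)
            index = construct.ld_clump(harm, e_geno, params)
            wt = construct.threshold_weights(harm, index, p_thr, source=f"{trait}:{grp}:p<{p_thr:g}")
            n_index[f"{trait}_{grp}_p{p_thr:g}"] = len(wt)
            if len(wt) == 0:
                continue
            label = f"{grp}_p{p_thr:g}"
            raw_e = construct.score_prs(e_geno, wt)
            std_e = construct.standardize_prs(raw_e, reference_raw=raw_e, reference_id="eval")
            if p_thr == config.component_threshold:
                construct.write_weight_table(wt, out / f"weights_{trait}_{grp}.tsv")
                written[f"weights_{trait}_{grp}.tsv"] = out / f"weights_{trait}_{grp}.tsv"
                components_eval[trait][label] = std_e
                raw_t = construct.score_prs(t_geno, wt)
                components_train[trait][label] = construct.standardize_prs(
                    raw_t, ref_constants=(std_e.ref_mean, std_e.ref_sd), reference_id="eval"
                )
                ref_constants[f"{trait}_{label}"] = (std_e.ref_mean, std_e.ref_sd)
    report["stages"]["construct"].update(
        n_index_variants=n_index, seconds=round(time.time() - t, 2)
    )

    # ---- cohort prep ---------------------------------------------------
    t = stage("prep")
    e_prep = cohort_mod.assign_strata(cohort_mod.adjust_for_medication(e_pheno))
    t_prep = cohort_mod.adjust_for_medication(t_pheno)
    unrelated = cohort_mod.select_unrelated(
        kin_table, threshold=config.kinship_threshold, ids=e_geno.ids
    )
    e_prep = e_prep.set_index("id")
    t_prep = t_prep.set_index("id")
    _write("phenotypes_prepped.tsv", io.write_pheno_tsv, e_prep.reset_index())
    (out / "unrelated_ids.txt").write_text("\n".join(sorted(unrelated)) + "\n")
    written["unrelated_ids.txt"] = out / "unrelated_ids.txt"
    report["stages"]["prep"].update(
        n_unrelated=len(unrelated), seconds=round(time.time() - t, 2)
    )

    # ---- combine -------------------------------------------------------
    t = stage("combine")
    covar_cols = ["age", "age2", "sex", "bmi"]
    for df in (e_prep, t_prep):
        df["age2"] = df["age"] ** 2
    prs_tables = {}
    for trait in ("sbp", "dbp"):
        comps_e = pd.DataFrame({k: v.scores for k, v in components_eval[trait].items()})
        comps_t = pd.DataFrame({k: v.scores for k, v in components_train[trait].items()})
        table = comps_e.copy()
        if comps_e.shape[1] >= 1:
            table["sum"] = combine_mod.sum_prs(comps_e)
            scope = config.combination_scope
            if scope == "per_group":
                wsum = pd.Series(np.nan, index=comps_e.index)
                for grp in base.n_individuals:
                    cw = combine_mod.train_combination_weights(
                        t_prep[f"{trait}_adj"] if f"{trait}_adj" in t_prep else t_prep[trait + "_adj"],
                        comps_t,
                        covariates=t_prep[covar_cols],
                        scope="per_group",
                        groups=t_prep["group"],
                        group=grp,
                    )
                    cw.to_json(out / f"combination_weights_{trait}_{grp}.json")
                    written[f"combination_weights_{trait}_{grp}.json"] = (
                        out / f"combination_weights_{trait}_{grp}.json"
                    )
                    mask = e_prep["group"] == grp
                    wsum[mask.to_numpy()] = combine_mod.weighted_sum_prs(comps_e[mask.to_numpy()], cw)
            else:
                cw = combine_mod.train_combination_weights(
                    t_prep[trait + "_adj"], comps_t, covariates=t_prep[covar_cols], scope="all"
                )
                cw.to_json(out / f"combination_weights_{trait}.json")
                written[f"combination_weights_{trait}.json"] = (
                    out / f"combination_weights_{trait}.json"
                )
                wsum = combine_mod.weighted_sum_prs(comps_e, cw)
            table["weighted_sum"] = wsum
        prs_tables[trait] = table
    report["stages"]["combine"].update(seconds=round(time.time() - t, 2))

    # ---- evaluate ------------------------------------------------------
    t = stage("evaluate")
    eval_rows = []
    for trait in ("sbp", "dbp"):
        res = evaluate.stratified_evaluation(
            e_prep,
            prs_tables[trait],
            covariate_cols=covar_cols,
            strata_spec=config.strata,
            traits=(trait + "_adj",),
            unrelated_ids=unrelated,
            group_col="group",
            min_n=config.min_stratum_n,
            n_boot=config.n_boot,
            seed=config.seed + 9000,
        )
        eval_rows.append(res)
    eval_table = pd.concat(eval_rows, ignore_index=True)
    eval_table.to_csv(out / "evaluation.tsv", sep="\t", index=False, float_format="%.6g")
    written["evaluation.tsv"] = out / "evaluation.tsv"

    # hypertension as a prevalent binary outcome: AUC of the combined score
    htn = ((e_prep["sbp_adj"] >= 140) | (e_prep["dbp_adj"] >= 90)).astype(int)
    combined_label = "sum" if "sum" in prs_tables["sbp"] else prs_tables["sbp"].columns[0]
    bp_score = prs_tables["sbp"][combined_label] + prs_tables["dbp"][combined_label]
    auc = evaluate.compute_auc(htn.to_numpy(), bp_score.to_numpy())
    report["stages"]["evaluate"].update(
        n_rows=len(eval_table), htn_auc=round(float(auc), 4), seconds=round(time.time() - t, 2)
    )

    # ---- ancestry diagnostics -----------------------------------------
    t = stage("ancestry")
    freq_table = anc_mod.estimate_ancestry_freqs(
        e_geno.dosages, e_geno.ancestry_proportions, e_geno.ancestry_names
    )
    props = pd.DataFrame(e_geno.ancestry_proportions, columns=e_geno.ancestry_names)
    groups80 = anc_mod.assign_ancestry_group(props, cutoff=config.ancestry_cutoff)
    trait_grp = next(iter(harmonized))
    harm0 = harmonized[trait_grp]
    clumped = construct.ld_clump(
        harm0, e_geno, construct.ClumpParams(config.r2_max, config.window_kb, 1.0)
    )
    idx = construct.variant_key(clumped)
    ft = freq_table.iloc[
        pd.Index(construct.variant_key(e_geno.variants)).get_indexer(idx)
    ].reset_index(drop=True)
    profile = anc_mod.effect_frequency_profile(clumped, ft, p_max=0.01)
    freq_table.to_csv(out / "ancestry_freqs.tsv", sep="\t", index=False, float_format="%.6g")
    profile.to_csv(out / "effect_frequency_profile.tsv", sep="\t", index=False, float_format="%.6g")
    written["ancestry_freqs.tsv"] = out / "ancestry_freqs.tsv"
    written["effect_frequency_profile.tsv"] = out / "effect_frequency_profile.tsv"
    report["stages"]["ancestry"].update(
        n_assigned=int(groups80.notna().sum()), seconds=round(time.time() - t, 2)
    )

    # ---- report --------------------------------------------------------
    for name, path in written.items():
        report["files"][name] = _sha256(path)
    report["seed"] = config.seed
    report["seconds_total"] = round(time.time() - t_all, 2)
    (out / "run_report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


def zlib_crc(text: str) -> int:
    import zlib

    return zlib.crc32(text.encode()) % 1000
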