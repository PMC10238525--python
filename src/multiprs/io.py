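"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: dosage matrices, phenotype/covariate tables,
sparse kinship triplets and summary statistics are tab-delimited; truth
sidecars are JSON; genotypes can also be exported as a minimal VCF with
hard GT calls (read back through pysam).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .simulate import GenotypeMatrix

__all__ = [
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_vcf",
    "read_vcf_dosages",
    "write_pheno_tsv",
    "read_pheno_tsv",
    "write_kinship_tsv",
    "read_kinship_tsv",
    "write_sumstats_tsv",
    "write_truth_json",
    "write_proportions_tsv",
    "read_proportions_tsv",
]


def write_dosage_tsv(genotypes: GenotypeMatrix, path):
    """Variant-major dosage matrix: metadata columns then one column per sample."""
    df = genotypes.variants.copy()
    mat = pd.DataFrame(
        genotypes.dosages.T, columns=genotypes.ids, index=df.index
    )
    pd.concat([df, mat], axis=1).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_dosage_tsv(path, proportions=None, ancestry_names=None, groups=None):
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["chrom", "pos", "other_allele", "effect_allele"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise InputError(f"dosage matrix lacks required columns: {missing}")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    dosages = df[sample_cols].to_numpy(float).T
    n = len(sample_cols)
    if proportions is None:
        proportions = np.ones((n, 1))
        ancestry_names = ancestry_names or ["ALL"]
    return GenotypeMatrix(
        dosages=dosages,
        variants=df[meta_cols].reset_index(drop=True),
        ids=np.array(sample_cols),
        ancestry_proportions=np.asarray(proportions, float),
        ancestry_names=list(ancestry_names),
        groups=None if groups is None else np.asarray(groups),
    )


def write_vcf(genotypes: GenotypeMatrix, path):
    """Minimal VCF 4.2 export with hard GT calls (dosages rounded)."""
    v = genotypes.variants
    ids = genotypes.ids
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    chroms = list(dict.fromkeys(v["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            maxpos = int(v.loc[v["chrom"].astype(str) == c, "pos"].max())
            fh.write(f"##contig=<ID={c},length={maxpos + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, ids)) + "\n")
        hard = np.rint(np.nan_to_num(genotypes.dosages)).astype(int)
        miss = np.isnan(genotypes.dosages)
        for j in range(genotypes.m):
            row = v.iloc[j]
            vid = f"{row.chrom}:{row.pos}:{row.other_allele}:{row.effect_allele}"
            calls = [
                "./." if miss[i, j] else gt_codes[int(hard[i, j])]
                for i in range(genotypes.n)
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{vid}\t{row.other_allele}\t"
                f"{row.effect_allele}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf_dosages(path):
    """Read a VCF into a GenotypeMatrix (ALT-allele dosage from GT or DS)."""
    import pysam

    vf = pysam.VariantFile(str(path))
    ids = np.array(list(vf.header.samples))
    rows, dos = [], []
    for rec in vf:
        rows.append((str(rec.chrom), rec.pos, rec.ref, rec.alts[0]))
        vals = np.full(len(ids), np.nan)
        for i, s in enumerate(ids):
            sm = rec.samples[s]
            if "DS" in sm and sm["DS"] is not None:
                vals[i] = float(sm["DS"])
            else:
                gt = sm.get("GT")
                if gt is not None and None not in gt:
                    vals[i] = float(sum(gt))
        dos.append(vals)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "other_allele", "effect_allele"])
    dosages = np.array(dos).T if dos else np.zeros((len(ids), 0))
    return GenotypeMatrix(
        dosages=dosages,
        variants=variants,
        ids=ids,
        ancestry_proportions=np.ones((len(ids), 1)),
        ancestry_names=["ALL"],
    )


def write_pheno_tsv(pheno: pd.DataFrame, path):
    pheno.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_pheno_tsv(path):
    return pd.read_csv(path, sep="\t")


def write_kinship_tsv(kin_table: pd.DataFrame, path):
    kin_table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_kinship_tsv(path):
    df = pd.read_csv(path, sep="\t")
    need = {"id1", "id2", "kinship"}
    if not need <= set(df.columns):
        raise InputError(f"kinship table must have columns {sorted(need)}")
    return df


def write_sumstats_tsv(sumstats: pd.DataFrame, path):
    cols = ["chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pval", "eaf", "n"]
    extra = [c for c in sumstats.columns if c not in cols]
    sumstats[cols + extra].to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_truth_json(truth: dict, path):
    def _conv(x):
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        raise TypeError(type(x))

    Path(path).write_text(json.dumps(truth, default=_conv, indent=1))


def write_proportions_tsv(genotypes: GenotypeMatrix, path):
    df = pd.DataFrame(genotypes.ancestry_proportions, columns=genotypes.ancestry_names)
    df.insert(0, "id", genotypes.ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_proportions_tsv(path):
    df = pd.read_csv(path, sep="\t")
    if "id" not in df.columns:
        raise InputError("proportions table needs an 'id' column")
    return df
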