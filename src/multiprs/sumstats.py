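"""GWAS summary-statistic reading, quality control and allele harmonization.

Summary statistics are held as pandas DataFrames with columns
``chrom, pos, effect_allele, other_allele, beta, se, pval, eaf, n``
(eaf and n may be absent or NaN).  Variants are matched to a target
genotype panel by (chrom, pos, unordered allele pair) on a single genome
build; positions are 1-based throughout, as in VCF.

Harmonization enforces the panel's counted allele: records whose effect
allele is the panel's other allele get their effect size negated and
frequency complemented; strand-ambiguous pairs (A/T, C/G) are removed,
because the strand cannot be resolved from the alleles alone.
Reverse-strand rescue is deliberately not attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import AmbiguityError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "REQUIRED_COLUMNS",
    "HarmonizationReport",
    "read_sumstats",
    "qc_filter",
    "harmonize_alleles",
    "panel_variants",
]

REQUIRED_COLUMNS = ("chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pval")
OPTIONAL_COLUMNS = ("eaf", "n")
_VALID_ALLELES = frozenset("ACGT")
_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class HarmonizationReport:
    """Bookkeeping of QC/harmonization; counts partition the input."""

    input: int = 0
    removed_maf: int = 0
    removed_missingness: int = 0
    removed_ambiguous: int = 0
    flipped: int = 0
    unmatched: int = 0
    retained: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def check_partition(self):
        total = (
            self.retained
            + self.removed_maf
            + self.removed_missingness
            + self.removed_ambiguous
            + self.unmatched
        )
        if total != self.input:
            raise AssertionError(
                f"report counts do not partition the input: {self.to_dict()}"
            )


def read_sumstats(path, column_map=None):
    """Read a summary-statistic TSV, mapping alternate headers via ``column_map``.

    ``column_map`` maps canonical names to the file's header names, e.g.
    ``{"pval": "P", "beta": "BETA"}``.  Malformed rows (non-ACGT or equal
    alleles, se <= 0, p outside (0,1], non-numeric fields) are dropped
    and counted in the log.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"summary statistics missing required column(s): {missing}")
    for c in OPTIONAL_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    df["chrom"] = df["chrom"].astype(str)
    for c in ("beta", "se", "pval", "eaf", "n"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    for c in ("effect_allele", "other_allele"):
        df[c] = df[c].astype(str).str.upper()

    n0 = len(df)
    ok = (
        df["pos"].notna()
        & df["beta"].notna()
        & df["se"].gt(0)
        & df["pval"].gt(0)
        & df["pval"].le(1)
        & df["effect_allele"].isin(_VALID_ALLELES)
        & df["other_allele"].isin(_VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
    )
    dropped = int(n0 - ok.sum())
    if dropped:
        logger.warning("read_sumstats: dropped %d malformed row(s) of %d", dropped, n0)
    out = df.loc[ok].reset_index(drop=True)
    out["pos"] = out["pos"].astype(int)
    return out


def panel_variants(genotypes):
    """Panel variant metadata (counted-allele frequency and missingness) from a GenotypeMatrix."""
    v = genotypes.variants.copy()
    v["eaf"] = genotypes.allele_frequencies()
    v["missingness"] = genotypes.missingness()
    return v


def qc_filter(sumstats, panel, maf_min=0.01, miss_max=0.01, strict_gwas_maf=False):
    """MAF/missingness filter against the target panel.

    Retains variants with MAF >= ``maf_min`` in both the GWAS (from its
    eaf column) and the panel, and panel missingness < ``miss_max``.
    Panel rows are matched on (chrom, pos); variants absent from the
    panel are counted as unmatched.  Records lacking a GWAS eaf pass the
    GWAS-side test unless ``strict_gwas_maf``.
    """
    report = HarmonizationReport(input=len(sumstats))
    p = panel.rename(columns={"eaf": "panel_eaf", "missingness": "panel_miss"})
    merged = sumstats.merge(
        p[["chrom", "pos", "panel_eaf", "panel_miss"]], on=["chrom", "pos"], how="left"
    )
    matched = merged["panel_eaf"].notna()
    report.unmatched = int((~matched).sum())

    panel_maf = np.minimum(merged["panel_eaf"], 1 - merged["panel_eaf"])
    gwas_maf = np.minimum(merged["eaf"], 1 - merged["eaf"])
    gwas_ok = gwas_maf >= maf_min
    if not strict_gwas_maf:
        gwas_ok = gwas_ok | merged["eaf"].isna()
    maf_ok = (panel_maf >= maf_min) & gwas_ok
    miss_ok = merged["panel_miss"] < miss_max

    fail_maf = matched & ~maf_ok
    fail_miss = matched & maf_ok & ~miss_ok
    keep = matched & maf_ok & miss_ok
    report.removed_maf = int(fail_maf.sum())
    report.removed_missingness = int(fail_miss.sum())
    report.retained = int(keep.sum())
    report.check_partition()
    if report.retained == 0:
        logger.warning("qc_filter: no variants retained")
    out = sumstats.loc[keep.to_numpy()].reset_index(drop=True)
    return out, report


def _is_ambiguous(a1, a2):
    return frozenset((a1, a2)) in _AMBIGUOUS_PAIRS


def harmonize_alleles(sumstats, panel):
    """Harmonize effect alleles to the panel's counted allele.

    Returns (harmonized, report).  The harmonized frame carries a boolean
    ``flipped`` column.  Panel rows must be unique per (chrom, pos);
    duplicated positions with conflicting allele pairs raise
    :class:`AmbiguityError`.
    """
    key = ["chrom", "pos"]
    pv = panel[key + ["other_allele", "effect_allele"]].copy()
    dup = pv.duplicated(subset=key, keep=False)
    if dup.any():
        pairs = pv.loc[dup].drop_duplicates()
        grp = pairs.groupby(key).size()
        conflicts = grp[grp > 1]
        if len(conflicts):
            raise AmbiguityError(
                "conflicting allele pairs at panel position(s): "
                + ", ".join(f"{c}:{p}" for c, p in conflicts.index)
            )
        pv = pv.drop_duplicates(subset=key)

    report = HarmonizationReport(input=len(sumstats))
    ambiguous = np.array(
        [_is_ambiguous(a, b) for a, b in zip(sumstats["effect_allele"], sumstats["other_allele"])]
    )
    report.removed_ambiguous = int(ambiguous.sum())
    ss = sumstats.loc[~ambiguous].reset_index(drop=True)

    merged = ss.merge(
        pv.rename(columns={"other_allele": "panel_other", "effect_allele": "panel_effect"}),
        on=key,
        how="left",
    )
    same = (merged["effect_allele"] == merged["panel_effect"]) & (
        merged["other_allele"] == merged["panel_other"]
    )
    swapped = (merged["effect_allele"] == merged["panel_other"]) & (
        merged["other_allele"] == merged["panel_effect"]
    )
    matched = same | swapped
    report.unmatched = int((~matched).sum())
    report.flipped = int(swapped.sum())
    report.retained = int(matched.sum())

    out = merged.loc[matched.to_numpy()].copy()
    sw = swapped.loc[matched].to_numpy()
    out["beta"] = np.where(sw, -out["beta"], out["beta"])
    out["eaf"] = np.where(sw, 1.0 - out["eaf"], out["eaf"])
    out["effect_allele"] = out["panel_effect"]
    out["other_allele"] = out["panel_other"]
    out["flipped"] = sw
    out = out.drop(columns=["panel_other", "panel_effect"]).reset_index(drop=True)

    if out.duplicated(subset=["chrom", "pos", "effect_allele", "other_allele"]).any():
        raise AmbiguityError("duplicate variant keys remain after harmonization")
    report.check_partition()
    return out, report
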