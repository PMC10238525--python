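"""Clump-and-threshold PRS construction, scoring and standardization.

LD clumping follows the greedy PRSice semantics: among variants passing
the p-value threshold, repeatedly select the most significant remaining
variant as an index SNP and remove every unselected variant on the same
chromosome within the distance window whose squared dosage correlation
with it (in the designated LD reference panel) exceeds the cutoff.
Removed ("clumped") variants can never seed a later clump.  Defaults are
r^2 = 0.1, window 1000 kb, thresholds {5e-8, 1e-5, 1e-2}.

Scoring is plain additive: PRS_j = sum_v weight_v * dosage_jv, with
missing dosages imputed as twice the effect-allele frequency by default.
Each PRS is standardized to mean 0 / SD 1 in a designated reference
cohort; external cohorts reuse the stored constants, so their scores are
on the reference scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError, InputError, ZeroVarianceError

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_P_THRESHOLDS",
    "ClumpParams",
    "StandardizedPRS",
    "ld_clump",
    "threshold_weights",
    "score_prs",
    "standardize_prs",
    "make_weight_table",
    "read_weight_table",
    "write_weight_table",
    "to_plink_score",
    "from_plink_score",
    "variant_key",
]

DEFAULT_P_THRESHOLDS = (5e-8, 1e-5, 1e-2)


@dataclass(frozen=True)
class ClumpParams:
    """Clumping parameters: r^2 cutoff, distance window (kb), p threshold."""

    r2_max: float = 0.1
    window_kb: float = 1000.0
    p_threshold: float = 1e-2

    def __post_init__(self):
        if not 0.0 < self.r2_max < 1.0:
            raise ConfigurationError("r2_max must lie in (0,1)")
        if self.window_kb <= 0:
            raise ConfigurationError("window_kb must be > 0")
        if not 0.0 < self.p_threshold <= 1.0:
            raise ConfigurationError("p_threshold must lie in (0,1]")


@dataclass
class StandardizedPRS:
    """Per-individual standardized score plus its reference constants."""

    scores: pd.Series
    ref_mean: float
    ref_sd: float
    reference_id: str = "reference"

    def __post_init__(self):
        if self.ref_sd <= 0:
            raise ZeroVarianceError("reference SD must be > 0")


def variant_key(df):
    """'chrom:pos:other:effect' string key for each row."""
    return (
        df["chrom"].astype(str)
        + ":"
        + df["pos"].astype(str)
        + ":"
        + df["other_allele"].astype(str)
        + ":"
        + df["effect_allele"].astype(str)
    )


def _align_to_panel(sumstats, genotypes):
    """Indices of each sumstat row's variant in the panel (exact key match)."""
    panel_keys = pd.Index(variant_key(genotypes.variants))
    idx = panel_keys.get_indexer(variant_key(sumstats))
    if (idx < 0).any():
        missing = variant_key(sumstats)[idx < 0].head(5).tolist()
        raise AlignmentError(
            f"{(idx < 0).sum()} sumstat variant(s) absent from the LD panel, e.g. {missing}"
        )
    return idx


def ld_clump(sumstats, ref_genotypes, params: ClumpParams):
    """Greedy LD clumping; returns the index-variant subset of ``sumstats``.

    The reference panel must contain every sumstat variant and at least
    two individuals.  Monomorphic panel variants have undefined r^2,
    treated as 0 (they can never be removed by LD with an index SNP).
    """
    if ref_genotypes.n < 2:
        raise InputError("LD reference panel needs >= 2 individuals")
    cand = sumstats.loc[sumstats["pval"] <= params.p_threshold].copy()
    if cand.empty:
        logger.warning("ld_clump: no variants pass p <= %g", params.p_threshold)
        return cand.reset_index(drop=True)

    # deterministic order: ascending p, ties by (chrom, pos)
    cand = cand.sort_values(["pval", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    col = _align_to_panel(cand, ref_genotypes)
    X = np.nan_to_num(ref_genotypes.dosages[:, col])
    Xc = X - X.mean(axis=0)
    norms = np.sqrt((Xc**2).sum(axis=0))
    mono = norms <= 0
    if mono.any():
        logger.info("ld_clump: %d monomorphic panel variant(s), r^2 treated as 0", mono.sum())

    chrom = cand["chrom"].to_numpy()
    pos = cand["pos"].to_numpy(float)
    window = params.window_kb * 1000.0

    alive = np.ones(len(cand), dtype=bool)
    selected = []
    for i in range(len(cand)):
        if not alive[i]:
            continue
        selected.append(i)
        near = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        near[i] = False
        if not near.any() or mono[i]:
            alive[i] = False
            continue
        j = np.flatnonzero(near)
        j = j[~mono[j]]
        if len(j):
            num = Xc[:, j].T @ Xc[:, i]
            r2 = (num / (norms[j] * norms[i])) ** 2
            alive[j[r2 > params.r2_max]] = False
        alive[i] = False
    out = cand.iloc[selected].reset_index(drop=True)
    return out


def threshold_weights(sumstats, index_set, p_threshold, source="C+T"):
    """Weight table: harmonized betas of index variants with p <= threshold."""
    keys = set(variant_key(index_set)) if len(index_set) else set()
    sel = variant_key(sumstats).isin(keys) & (sumstats["pval"] <= p_threshold)
    chosen = sumstats.loc[sel]
    return make_weight_table(chosen, chosen["beta"], source=source)


def make_weight_table(variants, weights, source="external"):
    """Assemble a weight table from variant metadata and per-variant weights."""
    wt = variants[["chrom", "pos", "other_allele", "effect_allele"]].copy().reset_index(drop=True)
    wt["weight"] = np.asarray(weights, dtype=float)
    if not np.isfinite(wt["weight"]).all():
        raise InputError("weights must be finite")
    wt["variant_id"] = variant_key(wt)
    if wt["variant_id"].duplicated().any():
        raise InputError("duplicate variant keys in weight table")
    wt["source"] = source
    return wt[["variant_id", "chrom", "pos", "other_allele", "effect_allele", "weight", "source"]]


def write_weight_table(wt, path):
    wt[["variant_id", "effect_allele", "weight", "source"]].to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )


def read_weight_table(path):
    df = pd.read_csv(path, sep="\t")
    need = {"variant_id", "effect_allele", "weight"}
    if not need <= set(df.columns):
        raise InputError(f"weight table must have columns {sorted(need)}")
    parts = df["variant_id"].str.split(":", expand=True)
    df["chrom"] = parts[0]
    df["pos"] = parts[1].astype(int)
    df["other_allele"] = parts[2]
    if "source" not in df.columns:
        df["source"] = "external"
    return df[["variant_id", "chrom", "pos", "other_allele", "effect_allele", "weight", "source"]]


def to_plink_score(wt, path):
    """Export as 3-column PLINK --score file (ID, effect allele, weight)."""
    wt[["variant_id", "effect_allele", "weight"]].to_csv(
        path, sep="\t", index=False, header=False, float_format="%.8g"
    )


def from_plink_score(path, source="plink"):
    df = pd.read_csv(path, sep="\t", header=None, names=["variant_id", "effect_allele", "weight"])
    parts = df["variant_id"].str.split(":", expand=True)
    if parts.shape[1] < 4:
        raise InputError("PLINK score IDs must be chrom:pos:other:effect")
    df["chrom"] = parts[0]
    df["pos"] = parts[1].astype(int)
    df["other_allele"] = parts[2]
    df["source"] = source
    return df[["variant_id", "chrom", "pos", "other_allele", "effect_allele", "weight", "source"]]


def score_prs(genotypes, weight_table, missing_policy="impute_eaf", strict=False):
    """Additive PRS: sum of weight x dosage over scored variants.

    Weight-table variants absent from the genotypes are dropped with a
    logged count (``strict=True`` raises).  Missing dosages follow
    ``missing_policy``: "impute_eaf" substitutes 2 x sample EAF,
    "renormalize" rescales each individual's score by the ratio of total
    to observed absolute weight.
    """
    panel_keys = pd.Index(variant_key(genotypes.variants))
    idx = panel_keys.get_indexer(weight_table["variant_id"])
    absent = idx < 0
    if absent.any():
        msg = f"score_prs: {absent.sum()} weight(s) absent from genotypes, dropped"
        if strict:
            raise AlignmentError(msg)
        logger.warning(msg)
    wt = weight_table.loc[~absent]
    cols = idx[~absent]
    mismatch = (
        wt["effect_allele"].to_numpy()
        != genotypes.variants["effect_allele"].to_numpy()[cols]
    )
    if mismatch.any():
        raise AlignmentError(
            "weight effect alleles not harmonized to genotype coding "
            f"({mismatch.sum()} mismatching variant(s))"
        )
    X = genotypes.dosages[:, cols]
    w = wt["weight"].to_numpy()
    if np.isnan(X).any():
        if missing_policy == "impute_eaf":
            fill = np.nanmean(X, axis=0)  # mean dosage == 2 * EAF
            X = np.where(np.isnan(X), fill, X)
            raw = X @ w
        elif missing_policy == "renormalize":
            obs = ~np.isnan(X)
            raw = np.nansum(X * w, axis=1)
            denom = (np.abs(w) * obs).sum(axis=1)
            total = np.abs(w).sum()
            with np.errstate(divide="ignore", invalid="ignore"):
                raw = np.where(denom > 0, raw * total / denom, 0.0)
        else:
            raise ConfigurationError(f"unknown missing_policy {missing_policy!r}")
    else:
        raw = X @ w
    return pd.Series(raw, index=pd.Index(genotypes.ids, name="id"), name="prs")


def standardize_prs(raw_prs, reference_raw=None, ref_constants=None, reference_id="reference"):
    """Center/scale a raw PRS to the reference cohort's mean 0 / SD 1.

    Pass either ``reference_raw`` (the raw scores of the reference
    cohort, from which mean/SD are computed) or precomputed
    ``ref_constants`` (mean, sd).  Standardizing the reference cohort by
    itself yields exactly mean 0, SD 1.
    """
    if (reference_raw is None) == (ref_constants is None):
        raise ConfigurationError("pass exactly one of reference_raw / ref_constants")
    if reference_raw is not None:
        mean = float(np.mean(reference_raw))
        sd = float(np.std(reference_raw, ddof=1))
    else:
        mean, sd = map(float, ref_constants)
    if sd <= 0 or not np.isfinite(sd):
        raise ZeroVarianceError("reference PRS has zero variance; cannot standardize")
    scores = (pd.Series(raw_prs) - mean) / sd
    scores.name = getattr(raw_prs, "name", "prs")
    return StandardizedPRS(scores=scores, ref_mean=mean, ref_sd=sd, reference_id=reference_id)
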