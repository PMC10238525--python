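"""Ancestry-specific allele frequencies and population-structure diagnostics.

In an admixed sample with known global ancestry proportions q_jk, the
expected dosage of individual j is E[x_j] = 2 * sum_k q_jk * p_k, where
p_k is the allele frequency in ancestry k.  ``estimate_ancestry_freqs``
solves this per variant by least squares with p_k constrained to [0,1]
— a global-proportions simplification of local-ancestry-aware frequency
estimators, unbiased when the admixture model holds.

Also provided: proportion rescaling after dropping a low-sample ancestry
(rows whose dropped fraction exceeds a cap are flagged excluded),
assignment of >=80%-ancestry groups, and the effect-size versus
ancestry-specific-frequency profile over clumped sub-significant
variants (the summary behind the observation that rarer variants carry
larger per-allele effects, giving a U-shaped |beta| profile against
frequency).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .errors import InputError, UnidentifiableError

__all__ = [
    "rescale_ancestry_proportions",
    "estimate_ancestry_freqs",
    "assign_ancestry_group",
    "effect_frequency_profile",
]


def rescale_ancestry_proportions(proportions, drop_label, max_dropped=0.05):
    """Drop one ancestry column and renormalize rows to sum to 1.

    ``proportions`` is a DataFrame with one column per ancestry (an 'id'
    column is preserved if present).  Rows whose dropped-ancestry
    fraction exceeds ``max_dropped`` are flagged ``excluded=True`` and
    not renormalized meaningfully (their proportions are left rescaled
    but should not be used).
    """
    df = proportions.copy()
    if drop_label not in df.columns:
        raise InputError(f"ancestry {drop_label!r} not in proportions table")
    anc_cols = [c for c in df.columns if c not in ("id", "excluded")]
    if np.abs(df[anc_cols].sum(axis=1) - 1.0).max() > 1e-6:
        raise InputError("proportion rows must sum to 1 before rescaling")
    dropped = df[drop_label]
    keep_cols = [c for c in anc_cols if c != drop_label]
    denom = df[keep_cols].sum(axis=1)
    out = df.drop(columns=[drop_label])
    with np.errstate(divide="ignore", invalid="ignore"):
        out[keep_cols] = df[keep_cols].div(denom.where(denom > 0), axis=0)
    out["excluded"] = dropped > max_dropped
    return out


def estimate_ancestry_freqs(dosages, ancestry_proportions, ancestry_names=None):
    """Per-variant ancestry-specific allele frequencies by constrained least squares.

    Solves min_p || dosage - 2 Q p ||^2 subject to 0 <= p_k <= 1 for each
    variant, Q the (n x K) proportions matrix.  Requires an identifiable
    ancestry design: collinear proportion columns raise
    :class:`UnidentifiableError` naming the ancestries.  Missing dosages
    are excluded row-wise per variant.  Returns a DataFrame with one
    frequency column per ancestry plus a residual-norm diagnostic.
    """
    X = np.asarray(dosages, float)
    Q = np.asarray(ancestry_proportions, float)
    n, m = X.shape
    k = Q.shape[1]
    if Q.shape[0] != n:
        raise InputError("dosages and proportions disagree on individual count")
    if n < k + 1:
        raise InputError(f"need at least K+1={k + 1} individuals")
    if ancestry_names is None:
        ancestry_names = [f"POP{i + 1}" for i in range(k)]
    rank = np.linalg.matrix_rank(Q, tol=1e-8)
    if rank < k:
        _, s, vt = np.linalg.svd(Q, full_matrices=False)
        null = vt[s <= s.max() * 1e-8]
        bad = sorted(
            {ancestry_names[j] for row in np.atleast_2d(null) for j in np.flatnonzero(np.abs(row) > 1e-6)}
        )
        raise UnidentifiableError(f"ancestry design collinear among {bad}")

    A_full = 2.0 * Q
    freqs = np.empty((m, k))
    resid = np.empty(m)
    any_nan = np.isnan(X).any()
    for v in range(m):
        x = X[:, v]
        if any_nan:
            ok = ~np.isnan(x)
            res = lsq_linear(A_full[ok], x[ok], bounds=(0.0, 1.0), method="bvls")
        else:
            res = lsq_linear(A_full, x, bounds=(0.0, 1.0), method="bvls")
        freqs[v] = res.x
        resid[v] = np.sqrt(2 * res.cost)
    out = pd.DataFrame(freqs, columns=ancestry_names)
    out["residual_norm"] = resid
    return out


def assign_ancestry_group(proportions, cutoff=0.8):
    """Label each row by the ancestry holding >= ``cutoff`` of its alleles.

    ``proportions``: DataFrame of ancestry columns (id/excluded columns
    ignored).  Rows with no ancestry at or above the cutoff — or flagged
    excluded — get None.
    """
    df = proportions
    anc_cols = [c for c in df.columns if c not in ("id", "excluded")]
    q = df[anc_cols].to_numpy(float)
    best = q.argmax(axis=1)
    label = np.where(
        q[np.arange(len(q)), best] >= cutoff,
        np.array(anc_cols, dtype=object)[best],
        None,
    )
    if "excluded" in df.columns:
        label = np.where(df["excluded"].to_numpy(bool), None, label)
    return pd.Series(label, index=df.index, name="ancestry_group")


def effect_frequency_profile(sumstats, ancestry_freq_table, p_max=0.01, n_bins=10):
    """|beta| summarized in ancestry-specific frequency bins.

    ``sumstats`` must already be restricted to clumped variants (see
    :func:`multiprs.construct.ld_clump`); rows are further filtered to
    p < ``p_max``.  For each ancestry column of ``ancestry_freq_table``
    (row-aligned to ``sumstats``), variants are binned by decile of that
    ancestry's frequency and |beta| is summarized per bin (n, median,
    quartiles).  Empty bins are absent from the output rather than
    reported as zero.
    """
    if len(sumstats) != len(ancestry_freq_table):
        raise InputError("sumstats and frequency table must be row-aligned")
    sel = (sumstats["pval"] < p_max).to_numpy()
    beta = np.abs(sumstats["beta"].to_numpy(float))[sel]
    rows = []
    anc_cols = [c for c in ancestry_freq_table.columns if c != "residual_norm"]
    for anc in anc_cols:
        f = ancestry_freq_table[anc].to_numpy(float)[sel]
        if len(f) == 0:
            continue
        edges = np.unique(np.quantile(f, np.linspace(0, 1, n_bins + 1)))
        if len(edges) < 2:
            edges = np.array([f.min() - 1e-9, f.max() + 1e-9])
        binned = np.clip(np.searchsorted(edges, f, side="right") - 1, 0, len(edges) - 2)
        for b in np.unique(binned):
            sub = beta[binned == b]
            rows.append(
                {
                    "ancestry": anc,
                    "bin": int(b),
                    "freq_lo": float(edges[b]),
                    "freq_hi": float(edges[b + 1]),
                    "n": int(len(sub)),
                    "median_abs_beta": float(np.median(sub)),
                    "q25_abs_beta": float(np.quantile(sub, 0.25)),
                    "q75_abs_beta": float(np.quantile(sub, 0.75)),
                }
            )
    return pd.DataFrame(rows)
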