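"""Combination of standardized component PRSs into multi-PRS scores.

Two combinations are supported: the simple (unweighted) sum of
standardized components, and the weighted sum w_1 PRS_1 + ... + w_k PRS_k
whose weights are the component coefficients from a single joint linear
regression of the trait on covariates plus all components, fit in an
independent training cohort.  Weight training can be restricted to the
background group that will be evaluated ("per-group" scope) or use all
training individuals.

``scale_match_prs`` addresses cross-dataset distribution shift (for
example from different imputation panels): "scale" equalizes SDs,
"scale_match" maps the source distribution onto the target one through a
monotone empirical-quantile mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    CollinearityError,
    ConfigurationError,
    InputError,
    ZeroVarianceError,
)

__all__ = [
    "CombinationWeights",
    "sum_prs",
    "train_combination_weights",
    "weighted_sum_prs",
    "scale_match_prs",
]


@dataclass
class CombinationWeights:
    """Trained multi-PRS weights plus training provenance."""

    labels: list[str]
    weights: list[float]
    cohort_id: str = "training"
    covariates: list[str] = field(default_factory=list)
    scope: str = "all"
    group: str | None = None

    def __post_init__(self):
        if len(self.labels) != len(self.weights):
            raise ConfigurationError("labels and weights must have equal length")
        if not np.all(np.isfinite(self.weights)):
            raise ConfigurationError("weights must be finite")

    def to_json(self, path=None):
        s = json.dumps(asdict(self), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            return cls(**json.load(fh))


def _component_frame(components):
    """Coerce dict/DataFrame of components (StandardizedPRS or Series) to a DataFrame."""
    if isinstance(components, pd.DataFrame):
        return components
    cols = {}
    for label, comp in components.items():
        cols[label] = comp.scores if hasattr(comp, "scores") else pd.Series(comp)
    df = pd.DataFrame(cols)
    if df.isna().any().any():
        raise AlignmentError("components are not defined on the same individuals")
    return df


def sum_prs(components):
    """Simple multi-PRS: elementwise sum of standardized components."""
    df = _component_frame(components)
    idxs = None
    if not isinstance(components, pd.DataFrame):
        for comp in components.values():
            s = comp.scores if hasattr(comp, "scores") else pd.Series(comp)
            if idxs is None:
                idxs = s.index
            elif not idxs.equals(s.index):
                raise AlignmentError("components are not aligned on the same individuals")
    out = df.sum(axis=1)
    out.name = "prs_sum"
    return out


def train_combination_weights(
    training_phenotype,
    components,
    covariates=None,
    scope="all",
    groups=None,
    group=None,
    cohort_id="training",
):
    """OLS training of multi-PRS weights in an independent cohort.

    Regresses the phenotype on [intercept, covariates, all components]
    jointly; the returned weights are the component coefficients.  With
    ``scope="per_group"``, rows are restricted to ``group`` (requires
    ``groups`` labels aligned to the phenotype).
    """
    comp = _component_frame(components)
    y = pd.Series(training_phenotype)
    if not comp.index.equals(y.index):
        comp = comp.reindex(y.index)
        if comp.isna().any().any():
            raise AlignmentError("components and phenotype cover different individuals")
    cov = None
    if covariates is not None and len(covariates.columns) > 0:
        cov = covariates.reindex(y.index)
        if cov.isna().any().any():
            raise AlignmentError("covariates and phenotype cover different individuals")

    if scope == "per_group":
        if groups is None or group is None:
            raise ConfigurationError("per_group scope requires groups= and group=")
        mask = np.asarray(pd.Series(groups).reindex(y.index) == group)
        if mask.sum() == 0:
            raise InputError(f"no training rows for group {group!r}")
        y = y[mask]
        comp = comp[mask]
        cov = cov[mask] if cov is not None else None
    elif scope != "all":
        raise ConfigurationError("scope must be 'all' or 'per_group'")

    blocks = [pd.Series(1.0, index=y.index, name="intercept")]
    if cov is not None:
        blocks.append(cov)
    blocks.append(comp)
    X = pd.concat(blocks, axis=1)
    Xm = X.to_numpy(float)
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        # name the columns spanning the null space
        _, s, vt = np.linalg.svd(Xm, full_matrices=False)
        null = vt[s < s.max() * 1e-10 * max(Xm.shape)] if (s < s.max() * 1e-8).any() else vt[-1:]
        offenders = sorted(
            {X.columns[j] for row in np.atleast_2d(null) for j in np.flatnonzero(np.abs(row) > 1e-6)}
        )
        raise CollinearityError(offenders)
    coef, *_ = np.linalg.lstsq(Xm, y.to_numpy(float), rcond=None)
    coefs = pd.Series(coef, index=X.columns)
    labels = list(comp.columns)
    return CombinationWeights(
        labels=labels,
        weights=[float(coefs[c]) for c in labels],
        cohort_id=cohort_id,
        covariates=[] if cov is None else list(cov.columns),
        scope=scope,
        group=group,
    )


def weighted_sum_prs(components, weights):
    """Weighted multi-PRS: sum_i w_i PRS_i, aligned by component label."""
    df = _component_frame(components)
    if isinstance(weights, CombinationWeights):
        missing = [l for l in weights.labels if l not in df.columns]
        if missing:
            raise AlignmentError(f"components missing labels {missing}")
        w = pd.Series(weights.weights, index=weights.labels)
        df = df[weights.labels]
    else:
        weights = np.asarray(weights, float)
        if len(weights) != df.shape[1]:
            raise AlignmentError("weight length does not match component count")
        w = pd.Series(weights, index=df.columns)
    out = df.to_numpy(float) @ w.to_numpy()
    return pd.Series(out, index=df.index, name="prs_weighted_sum")


def scale_match_prs(prs_values, source_values, target_values, mode="none"):
    """Cross-dataset PRS rescaling.

    mode="none": identity.  mode="scale": multiply by target SD / source
    SD (distribution location untouched beyond reference
    standardization).  mode="scale_match": monotone empirical-quantile
    mapping — each value's midrank quantile within the source sample is
    mapped to the corresponding empirical quantile of the target sample
    (linear interpolation between order statistics).
    """
    x = np.asarray(prs_values, float)
    src = np.asarray(source_values, float)
    tgt = np.asarray(target_values, float)
    if mode == "none":
        out = x.copy()
    elif mode == "scale":
        if len(src) < 2 or len(tgt) < 2:
            raise InputError("scale mode needs >= 2 source and target values")
        s_sd = src.std(ddof=1)
        t_sd = tgt.std(ddof=1)
        if s_sd <= 0:
            raise ZeroVarianceError("source SD is zero")
        out = x * (t_sd / s_sd)
    elif mode == "scale_match":
        if len(tgt) == 0 or len(src) == 0:
            raise InputError("scale_match needs nonempty source and target samples")
        src_sorted = np.sort(src)
        n = len(src_sorted)
        # interpolated empirical CDF position within the source sample:
        # strictly increasing on the source range, so ranks are preserved
        grid = (np.arange(1, n + 1) - 0.5) / n
        u = np.interp(x, src_sorted, grid)
        out = np.quantile(tgt, np.clip(u, 0.0, 1.0), method="linear")
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    if isinstance(prs_values, pd.Series):
        return pd.Series(out, index=prs_values.index, name=prs_values.name)
    return out
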