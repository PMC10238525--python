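"""PRS association models and percent-variance-explained evaluation.

The association model regresses a BP trait on covariates plus a
standardized PRS, optionally with group-specific intercepts (study x
background combinations), group-specific residual variances fit by
feasible generalized least squares (FGLS), and a polygenic random effect
with covariance sigma2_g * 2K for a kinship matrix K.  The PRS effect is
reported per reference-cohort SD with a two-sided one-degree-of-freedom
Wald test.

PVE (percent variance explained) follows

    PVE = (1 - sigma2_prs / sigma2_null) * 100,

where sigma2_prs and sigma2_null are the residual variances of the
models with and without the PRS, computed on an unrelated subset.  With
homogeneous variances this equals the partial R-squared of the PRS given
the covariates.  Confidence intervals use the percentile bootstrap
(resampling unrelated individuals; 2.5th/97.5th percentiles; 1000
replicates by default).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CollinearityError,
    ConvergenceError,
    InputError,
    NumericalError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationFit",
    "PVEResult",
    "fit_association",
    "compute_pve",
    "bootstrap_pve_ci",
    "stratified_evaluation",
    "compute_auc",
]


@dataclass
class AssociationFit:
    beta_prs: float
    se: float
    pval: float
    coefficients: pd.Series
    group_variances: dict = field(default_factory=dict)
    n: int = 0
    sigma2_g: float | None = None
    converged: bool = True

    def __post_init__(self):
        if self.se <= 0:
            raise NumericalError("Wald SE must be > 0")


@dataclass
class PVEResult:
    sigma2_prs: float
    sigma2_null: float
    pve: float
    ci_lo: float | None = None
    ci_hi: float | None = None
    n_unrelated: int = 0
    stratum: str = "all"

    def __post_init__(self):
        if self.sigma2_prs <= 0 or self.sigma2_null <= 0:
            raise NumericalError("residual variances must be > 0")
        if self.ci_lo is not None and self.ci_hi is not None and self.ci_lo > self.ci_hi:
            raise NumericalError("bootstrap CI bounds out of order")


def _build_design(covariates, group_intercepts, prs, index=None):
    blocks = []
    if group_intercepts is not None:
        dummies = pd.get_dummies(pd.Series(group_intercepts), prefix="grp", dtype=float)
        blocks.append(dummies)
    else:
        if index is None:
            index = covariates.index if covariates is not None else pd.Series(prs).index
        blocks.append(pd.Series(1.0, index=index, name="intercept").to_frame())
    if covariates is not None and covariates.shape[1] > 0:
        blocks.append(covariates.astype(float))
    if prs is not None:
        blocks.append(pd.Series(prs, name="prs").to_frame())
    X = pd.concat(blocks, axis=1)
    return X


def _check_rank(Xm, columns):
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        _, s, vt = np.linalg.svd(Xm, full_matrices=False)
        null = vt[s <= s.max() * 1e-10 * max(Xm.shape)]
        if null.size == 0:
            null = vt[-1:]
        offenders = sorted(
            {columns[j] for row in np.atleast_2d(null) for j in np.flatnonzero(np.abs(row) > 1e-6)}
        )
        raise CollinearityError(offenders)


def _fgls(Xm, y, group_codes, n_groups, max_iter=50, tol=1e-8):
    """Iterative FGLS; returns (beta, cov_beta, group_variances, n_iter)."""
    n, p = Xm.shape
    sig2 = np.ones(n_groups)
    trace = []
    for it in range(max_iter):
        w = 1.0 / sig2[group_codes]
        Xw = Xm * w[:, None]
        XtWX = Xw.T @ Xm
        XtWy = Xw.T @ y
        beta = np.linalg.solve(XtWX, XtWy)
        resid = y - Xm @ beta
        new = np.array(
            [
                np.mean(resid[group_codes == g] ** 2) if (group_codes == g).any() else sig2[g]
                for g in range(n_groups)
            ]
        )
        new = np.maximum(new, 1e-12)
        rel = np.max(np.abs(new - sig2) / np.maximum(sig2, 1e-12))
        trace.append(rel)
        sig2 = new
        if rel < tol:
            break
    else:
        raise ConvergenceError(
            f"FGLS did not converge in {max_iter} iterations", trace=trace
        )
    w = 1.0 / sig2[group_codes]
    cov = np.linalg.inv((Xm * w[:, None]).T @ Xm)
    return beta, cov, sig2, it + 1


def _kinship_fit(Xm, y, K2, max_iter=60):
    """Two-variance-component fit: y = Xb + g + e, var = s2*(phi*2K + (1-phi) I).

    Profiles the ML likelihood over phi = sigma2_g / sigma2_total using
    the eigendecomposition of 2K; grid search refined by golden section.
    """
    s_eig, U = np.linalg.eigh(K2)
    if s_eig.min() < -1e-8 * max(1.0, s_eig.max()):
        raise NumericalError("kinship matrix (2K) is not positive semi-definite")
    s_eig = np.maximum(s_eig, 0.0)
    yt = U.T @ y
    Xt = U.T @ Xm
    n = len(y)

    def negloglik(phi):
        d = phi * s_eig + (1.0 - phi)
        d = np.maximum(d, 1e-12)
        w = 1.0 / d
        XtWX = (Xt * w[:, None]).T @ Xt
        beta = np.linalg.solve(XtWX, (Xt * w[:, None]).T @ yt)
        r = yt - Xt @ beta
        s2 = float(np.sum(w * r**2) / n)
        return 0.5 * (n * np.log(max(s2, 1e-300)) + np.sum(np.log(d)) + n), beta, s2, XtWX

    grid = np.concatenate([[0.0], np.geomspace(1e-4, 0.99, 25)])
    vals = [negloglik(p)[0] for p in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    gr = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - gr * (b - a), a + gr * (b - a)
    fc, fd = negloglik(c)[0], negloglik(d)[0]
    for _ in range(max_iter):
        if b - a < 1e-6:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = negloglik(c)[0]
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = negloglik(d)[0]
    phi = (a + b) / 2
    if negloglik(0.0)[0] <= negloglik(phi)[0]:
        phi = 0.0
    _, beta, s2, XtWX = negloglik(phi)
    cov = np.linalg.inv(XtWX) * s2
    return beta, cov, phi, s2


def fit_association(
    pheno,
    prs,
    covariates=None,
    group_intercepts=None,
    variance_groups=None,
    kinship=None,
    max_iter=50,
    tol=1e-8,
    fixed_variances=None,
):
    """Fit the PRS association model; see module docstring for the model.

    ``pheno`` and ``prs`` are aligned Series; ``covariates`` a DataFrame;
    ``group_intercepts``/``variance_groups`` label Series;``kinship`` a
    dense kinship matrix aligned to the rows (the model uses 2K).  Rows
    with any missing model variable are dropped (count logged).  With
    both ``variance_groups`` and ``kinship``, rows are first whitened by
    the FGLS group SDs, then the polygenic component is profiled on the
    whitened data.  ``fixed_variances`` (a mapping from variance-group
    label to residual variance) bypasses the FGLS iteration and fits a
    single weighted least squares with the given variances.
    """
    y = pd.Series(pheno).astype(float)
    X = _build_design(covariates, group_intercepts, prs)
    keep = y.notna() & X.notna().all(axis=1)
    if variance_groups is not None:
        keep &= pd.Series(variance_groups).notna()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("fit_association: dropped %d incomplete row(s)", n_drop)
    if kinship is not None and n_drop:
        kin_idx = np.flatnonzero(keep.to_numpy())
        kinship = np.asarray(kinship)[np.ix_(kin_idx, kin_idx)]
    y = y[keep]
    X = X.loc[keep]
    Xm = X.to_numpy(float)
    yv = y.to_numpy(float)
    n = len(yv)
    if n <= Xm.shape[1] + 1:
        raise InputError("too few complete rows for the design")
    _check_rank(Xm, list(X.columns))

    if variance_groups is not None:
        vg = pd.Series(variance_groups)[keep]
        codes, uniques = pd.factorize(vg)
    else:
        codes, uniques = np.zeros(n, dtype=int), pd.Index(["all"])

    sigma2_g = None
    if kinship is None:
        if fixed_variances is not None:
            sig2 = np.array([float(fixed_variances[g]) for g in uniques])
            w = 1.0 / sig2[codes]
            Xw = Xm * w[:, None]
            XtWX = Xw.T @ Xm
            beta = np.linalg.solve(XtWX, Xw.T @ yv)
            cov = np.linalg.inv(XtWX)
        else:
            beta, cov, sig2, _ = _fgls(Xm, yv, codes, len(uniques), max_iter, tol)
        group_vars = dict(zip(uniques, sig2))
    else:
        K2 = 2.0 * np.asarray(kinship, float)
        if len(uniques) > 1:
            # whiten by FGLS group SDs, then profile the polygenic
            # component on the rescaled data (kinship rescaled to match)
            _, _, sig2, _ = _fgls(Xm, yv, codes, len(uniques), max_iter, tol)
            sd = np.sqrt(sig2[codes])
            beta, cov_w, phi, s2 = _kinship_fit(
                Xm / sd[:, None], yv / sd, K2 / np.outer(sd, sd)
            )
            # map the covariance of beta back to the original scale: the
            # whitened fit already estimates beta on the original scale
            cov = cov_w
            group_vars = dict(zip(uniques, (1.0 - phi) * s2 * sig2))
            sigma2_g = phi * s2 * float(np.mean(sig2))
        else:
            beta, cov, phi, s2 = _kinship_fit(Xm, yv, K2)
            group_vars = {"all": (1.0 - phi) * s2}
            sigma2_g = phi * s2

    coefs = pd.Series(beta, index=X.columns)
    j = X.columns.get_loc("prs") if prs is not None else None
    if j is None:
        raise InputError("fit_association requires a PRS column")
    se = float(np.sqrt(cov[j, j]))
    z = coefs["prs"] / se
    pval = float(min(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny), 1.0))
    return AssociationFit(
        beta_prs=float(coefs["prs"]),
        se=se,
        pval=pval,
        coefficients=coefs,
        group_variances={str(k): float(v) for k, v in group_vars.items()},
        n=n,
        sigma2_g=None if sigma2_g is None else float(sigma2_g),
    )


def _rss_null_full(X0, prs_vec, yv):
    """Residual sums of squares of the covariate-only and covariate+PRS models.

    One QR factorization with the PRS as the last column yields both: the
    null RSS exceeds the full RSS by the squared projection of y on the
    last orthonormal direction.
    """
    X1 = np.column_stack([X0, prs_vec])
    Q, R = np.linalg.qr(X1)
    if np.abs(np.diag(R)).min() <= 1e-10 * max(np.abs(np.diag(R)).max(), 1.0):
        raise np.linalg.LinAlgError("singular design")
    qy = Q.T @ yv
    rss_full = float(yv @ yv - qy @ qy)
    rss_null = rss_full + float(qy[-1] ** 2)
    return rss_null, rss_full


def compute_pve(
    pheno,
    prs,
    covariates=None,
    unrelated_ids=None,
    group_intercepts=None,
    variance_groups=None,
    variance_handling="homogeneous",
    stratum="all",
):
    """Point estimate of PVE = (1 - sigma2_prs / sigma2_null) * 100.

    Fits the covariates-only and covariates+PRS models on the unrelated
    subset.  ``variance_handling="homogeneous"`` uses sigma2 = RSS / n in
    both models (so PVE is exactly the PRS's partial R-squared);
    ``"pooled"`` runs per-group FGLS and pools the group residual
    variances by their degrees of freedom.  Negative PVE is reported
    as-is.
    """
    y = pd.Series(pheno).astype(float)
    if unrelated_ids is not None:
        sel = y.index.isin(set(unrelated_ids))
        y = y[sel]
        prs = pd.Series(prs)[sel]
        covariates = covariates.loc[y.index] if covariates is not None else None
        if group_intercepts is not None:
            group_intercepts = pd.Series(group_intercepts)[sel]
        if variance_groups is not None:
            variance_groups = pd.Series(variance_groups)[sel]
    X = _build_design(covariates, group_intercepts, None, index=y.index)
    keep = y.notna() & X.notna().all(axis=1) & pd.Series(prs).notna()
    y, X = y[keep], X.loc[keep]
    prs_v = pd.Series(prs)[keep].to_numpy(float)
    n = len(y)
    if n < X.shape[1] + 3:
        raise InputError(f"insufficient unrelated individuals (n={n}) for PVE")
    X0 = X.to_numpy(float)
    yv = y.to_numpy(float)
    _check_rank(np.column_stack([X0, prs_v]), list(X.columns) + ["prs"])

    if variance_handling == "homogeneous" or variance_groups is None:
        rss_null, rss_full = _rss_null_full(X0, prs_v, yv)
        s_null, s_full = rss_null / n, rss_full / n
    elif variance_handling == "pooled":
        codes, uniques = pd.factorize(pd.Series(variance_groups)[keep.to_numpy()])
        _, _, sig2_null, _ = _fgls(X0, yv, codes, len(uniques))
        _, _, sig2_full, _ = _fgls(np.column_stack([X0, prs_v]), yv, codes, len(uniques))
        counts = np.bincount(codes, minlength=len(uniques)).astype(float)
        df = np.maximum(counts - 1.0, 1.0)
        s_null = float(np.sum(df * sig2_null) / df.sum())
        s_full = float(np.sum(df * sig2_full) / df.sum())
    else:
        raise InputError(f"unknown variance_handling {variance_handling!r}")
    pve = (1.0 - s_full / s_null) * 100.0
    return PVEResult(
        sigma2_prs=s_full, sigma2_null=s_null, pve=pve, n_unrelated=n, stratum=stratum
    )


def bootstrap_pve_ci(
    pheno,
    prs,
    covariates=None,
    unrelated_ids=None,
    group_intercepts=None,
    n_boot=1000,
    seed=0,
    alpha=0.05,
    max_retries=10,
):
    """Percentile-bootstrap CI for PVE.

    Resamples unrelated individuals with replacement ``n_boot`` times and
    recomputes the PVE each time; the CI is the empirical alpha/2 and
    1-alpha/2 percentiles.  Replicates with singular resampled designs
    are redrawn (up to ``max_retries``, logged).
    """
    y = pd.Series(pheno).astype(float)
    if unrelated_ids is not None:
        sel = y.index.isin(set(unrelated_ids))
        y = y[sel]
        prs = pd.Series(prs)[sel]
        covariates = covariates.loc[y.index] if covariates is not None else None
        if group_intercepts is not None:
            group_intercepts = pd.Series(group_intercepts)[sel]
    X = _build_design(covariates, group_intercepts, None, index=y.index)
    keep = y.notna() & X.notna().all(axis=1) & pd.Series(prs).notna()
    y, X = y[keep], X.loc[keep]
    prs_v = pd.Series(prs)[keep].to_numpy(float)
    X0 = X.to_numpy(float)
    yv = y.to_numpy(float)
    n = len(yv)
    rng = np.random.default_rng(seed)
    stats_out = np.empty(n_boot)
    n_redraw = 0
    for b in range(n_boot):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, n)
            try:
                rss_null, rss_full = _rss_null_full(X0[idx], prs_v[idx], yv[idx])
                stats_out[b] = (1.0 - rss_full / rss_null) * 100.0
                break
            except np.linalg.LinAlgError:
                n_redraw += 1
        else:
            raise NumericalError("bootstrap replicate singular after retries")
    if n_redraw:
        logger.info("bootstrap_pve_ci: redrew %d singular replicate(s)", n_redraw)
    lo, hi = np.percentile(stats_out, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def stratified_evaluation(
    pheno,
    prs_table,
    covariate_cols,
    strata_spec,
    traits=("sbp_adj", "dbp_adj"),
    unrelated_ids=None,
    group_col=None,
    min_n=50,
    n_boot=0,
    seed=0,
):
    """Association + PVE per stratum x trait x PRS.

    ``pheno`` holds traits, covariates and stratum label columns (from
    :func:`multiprs.cohort.assign_strata`); ``prs_table`` is a DataFrame of
    standardized PRS columns aligned to ``pheno``'s index.  ``strata_spec``
    lists stratum label columns; each level of each column becomes one
    stratum (missing labels excluded).  Strata below ``min_n`` are
    skipped with a warning.  Set ``n_boot`` > 0 for bootstrap CIs.
    Returns a tidy DataFrame.
    """
    rows = []
    prs_table = prs_table.reindex(pheno.index)
    for strat_col in strata_spec:
        if strat_col == "all":
            levels = [("all", pd.Series(True, index=pheno.index))]
        else:
            vals = pheno[strat_col]
            levels = [
                (str(lv), vals == lv) for lv in pd.unique(vals.dropna())
            ]
        for label, mask in levels:
            sub = pheno.loc[mask]
            if len(sub) < min_n:
                logger.warning(
                    "stratified_evaluation: stratum %s=%s has n=%d < %d, skipped",
                    strat_col, label, len(sub), min_n,
                )
                continue
            cov = sub[list(covariate_cols)].astype(float)
            # covariates constant within the stratum (e.g. sex inside a sex
            # stratum) carry no information and would make the design singular
            cov = cov.loc[:, cov.nunique() > 1]
            gi = sub[group_col] if group_col is not None and sub[group_col].nunique() > 1 else None
            for trait in traits:
                for prs_label in prs_table.columns:
                    prs = prs_table.loc[sub.index, prs_label]
                    try:
                        fit = fit_association(sub[trait], prs, cov, group_intercepts=gi)
                        pve = compute_pve(
                            sub[trait], prs, cov,
                            unrelated_ids=unrelated_ids,
                            group_intercepts=gi,
                            stratum=f"{strat_col}={label}",
                        )
                    except (InputError, NumericalError) as exc:
                        logger.warning("stratum %s=%s %s %s failed: %s", strat_col, label, trait, prs_label, exc)
                        continue
                    ci_lo = ci_hi = np.nan
                    if n_boot > 0:
                        ci_lo, ci_hi = bootstrap_pve_ci(
                            sub[trait], prs, cov,
                            unrelated_ids=unrelated_ids,
                            group_intercepts=gi,
                            n_boot=n_boot,
                            seed=seed
                            + zlib.crc32(f"{strat_col}|{label}|{trait}|{prs_label}".encode())
                            % 2**16,
                        )
                    rows.append(
                        {
                            "stratum_var": strat_col,
                            "stratum": label,
                            "trait": trait,
                            "prs_label": prs_label,
                            "n": fit.n,
                            "beta": fit.beta_prs,
                            "se": fit.se,
                            "pval": fit.pval,
                            "pve": pve.pve,
                            "ci_lo": ci_lo,
                            "ci_hi": ci_hi,
                            "n_unrelated": pve.n_unrelated,
                        }
                    )
    return pd.DataFrame(rows)


def compute_auc(binary_outcome, score):
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    y = np.asarray(binary_outcome)
    s = np.asarray(score, float)
    if set(np.unique(y)) - {0, 1, True, False}:
        raise InputError("binary outcome must be coded 0/1")
    y = y.astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise InputError("AUC undefined: outcome has a single class")
    ranks = stats.rankdata(s)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))
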