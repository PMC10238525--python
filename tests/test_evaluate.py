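"""Association fits, PVE, bootstrap CIs, stratified evaluation and AUC."""

import numpy as np
import pandas as pd
import pytest

from multiprs import evaluate
from multiprs.errors import CollinearityError, InputError, NumericalError
from oracles import pair_counting_auc


def make_data(n=1000, beta=2.0, resid_sd=1.0, seed=0, groups=None, group_sds=None):
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"I{i}" for i in range(n)], name="id")
    prs = pd.Series(rng.standard_normal(n), index=idx, name="prs")
    cov = pd.DataFrame({"age": rng.uniform(20, 80, n), "sex": rng.integers(0, 2, n)}, index=idx)
    if groups is not None:
        sds = np.array([group_sds[g] for g in groups])
    else:
        sds = resid_sd
    y = pd.Series(
        10 + 0.1 * cov["age"] + 1.5 * cov["sex"] + beta * prs + rng.standard_normal(n) * sds,
        index=idx,
        name="y",
    )
    return y, prs, cov


class TestFitAssociation:
    def test_single_group_reduces_to_ols(self):
        y, prs, cov = make_data(n=400, seed=1)
        fit = evaluate.fit_association(y, prs, cov)
        X = np.column_stack([np.ones(400), cov["age"], cov["sex"], prs])
        ols = np.linalg.lstsq(X, y.to_numpy(), rcond=None)[0]
        assert fit.beta_prs == pytest.approx(ols[-1], abs=1e-10)

    def test_heteroskedastic_variance_ratio_recovered(self):
        n = 8000
        groups = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        y, prs, cov = make_data(n=n, seed=2, groups=groups, group_sds={"a": 1.0, "b": 2.0})
        fit = evaluate.fit_association(y, prs, cov, variance_groups=pd.Series(groups, index=y.index))
        ratio = fit.group_variances["b"] / fit.group_variances["a"]
        assert abs(ratio - 4.0) < 0.3

    def test_fixed_true_variances_match_closed_form_wls(self):
        n = 2000
        groups = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        y, prs, cov = make_data(n=n, seed=3, groups=groups, group_sds={"a": 1.0, "b": 2.0})
        fit = evaluate.fit_association(
            y, prs, cov,
            variance_groups=pd.Series(groups, index=y.index),
            fixed_variances={"a": 1.0, "b": 4.0},
        )
        X = np.column_stack([np.ones(n), cov["age"], cov["sex"], prs])
        w = np.where(groups == "a", 1.0, 0.25)
        beta_wls = np.linalg.solve((X * w[:, None]).T @ X, (X * w[:, None]).T @ y.to_numpy())
        assert fit.beta_prs == pytest.approx(beta_wls[-1], abs=1e-6)

    def test_null_kinship_effect_hits_boundary(self):
        rng = np.random.default_rng(4)
        y, prs, cov = make_data(n=300, seed=4)
        # PSD kinship with off-diagonal structure but no true polygenic effect
        A = rng.standard_normal((300, 80))
        kin = (A @ A.T) / 160 / 2
        fit_k = evaluate.fit_association(y, prs, cov, kinship=kin)
        fit_0 = evaluate.fit_association(y, prs, cov)
        assert fit_k.sigma2_g == pytest.approx(0.0, abs=0.3 * fit_0.group_variances["all"])
        assert fit_k.beta_prs == pytest.approx(fit_0.beta_prs, abs=5e-3 * abs(fit_0.beta_prs) + 1e-6)

    def test_polygenic_component_detected(self):
        rng = np.random.default_rng(5)
        n = 400
        blocks = 100
        fam = np.repeat(np.arange(blocks), n // blocks)
        kin = (fam[:, None] == fam[None, :]) * 0.25
        np.fill_diagonal(kin, 0.5)
        L = np.linalg.cholesky(2 * kin + 1e-8 * np.eye(n))
        g = L @ rng.standard_normal(n) * 2.0
        y, prs, cov = make_data(n=n, beta=0.5, seed=6)
        y = y + g
        fit = evaluate.fit_association(y, prs, cov, kinship=kin)
        assert fit.sigma2_g > 0.5

    def test_singular_design_names_columns(self):
        y, prs, cov = make_data(n=100, seed=7)
        cov["age_copy"] = cov["age"]
        with pytest.raises(CollinearityError) as exc:
            evaluate.fit_association(y, prs, cov)
        assert "age_copy" in exc.value.columns


class TestComputePve:
    def test_null_prs_explains_nothing(self):
        y, prs, cov = make_data(n=5000, beta=0.0, resid_sd=3.0, seed=8)
        res = evaluate.compute_pve(y, prs, cov)
        assert abs(res.pve) < 0.5

    def test_arithmetic_of_the_definition(self):
        res = evaluate.PVEResult(sigma2_prs=3.0, sigma2_null=4.0, pve=25.0)
        assert res.pve == pytest.approx((1 - 3 / 4) * 100)

    def test_variance_decomposition_oracle(self):
        # y = 3 * standardized PRS + e, Var(e) = 91 -> PVE -> 9/100
        rng = np.random.default_rng(9)
        n = 10_000
        idx = pd.Index([f"I{i}" for i in range(n)])
        prs = pd.Series(rng.standard_normal(n), index=idx)
        prs = (prs - prs.mean()) / prs.std(ddof=1)
        y = 3.0 * prs + rng.standard_normal(n) * np.sqrt(91.0)
        res = evaluate.compute_pve(y, prs)
        assert abs(res.pve - 9.0) < 1.0

    def test_insufficient_unrelated_rejected(self):
        y, prs, cov = make_data(n=100, seed=10)
        with pytest.raises(InputError):
            evaluate.compute_pve(y, prs, cov, unrelated_ids={"I0", "I1", "I2"})

    def test_affine_invariance(self):
        y, prs, cov = make_data(n=800, seed=11)
        base = evaluate.compute_pve(y, prs, cov)
        fit_base = evaluate.fit_association(y, prs, cov)
        scaled = evaluate.compute_pve(y, -2.5 * prs + 7.0, cov)
        fit_scaled = evaluate.fit_association(y, -2.5 * prs + 7.0, cov)
        assert scaled.pve == pytest.approx(base.pve, abs=1e-10)
        assert fit_scaled.pval == pytest.approx(fit_base.pval, abs=1e-10)

    def test_equals_partial_r_squared(self):
        """PVE == (R2_full - R2_null) / (1 - R2_null) for homogeneous variances."""
        y, prs, cov = make_data(n=600, seed=12)
        res = evaluate.compute_pve(y, prs, cov)
        X0 = np.column_stack([np.ones(600), cov.to_numpy()])
        X1 = np.column_stack([X0, prs.to_numpy()])
        yv = y.to_numpy()
        tss = np.sum((yv - yv.mean()) ** 2)
        rss0 = np.sum((yv - X0 @ np.linalg.lstsq(X0, yv, rcond=None)[0]) ** 2)
        rss1 = np.sum((yv - X1 @ np.linalg.lstsq(X1, yv, rcond=None)[0]) ** 2)
        r2_0, r2_1 = 1 - rss0 / tss, 1 - rss1 / tss
        assert res.pve / 100 == pytest.approx((r2_1 - r2_0) / (1 - r2_0), abs=1e-10)

    def test_pooled_variance_handling_close_to_homogeneous_under_homoskedasticity(self):
        n = 2000
        groups = pd.Series(["a", "b"] * (n // 2))
        y, prs, cov = make_data(n=n, seed=13)
        groups.index = y.index
        hom = evaluate.compute_pve(y, prs, cov)
        pooled = evaluate.compute_pve(
            y, prs, cov, variance_groups=groups, variance_handling="pooled"
        )
        assert abs(hom.pve - pooled.pve) < 0.5


class TestBootstrap:
    def test_deterministic_under_seed(self):
        y, prs, cov = make_data(n=300, seed=14)
        a = evaluate.bootstrap_pve_ci(y, prs, cov, n_boot=50, seed=9)
        b = evaluate.bootstrap_pve_ci(y, prs, cov, n_boot=50, seed=9)
        assert a == b

    def test_degenerate_statistic_zero_width(self):
        rng = np.random.default_rng(15)
        idx = pd.Index([f"I{i}" for i in range(200)])
        prs = pd.Series(rng.standard_normal(200), index=idx)
        y = 2.0 * prs  # no noise: every replicate has PVE exactly 100
        lo, hi = evaluate.bootstrap_pve_ci(y, prs, n_boot=40, seed=16)
        assert lo == pytest.approx(100.0, abs=1e-8)
        assert hi == pytest.approx(100.0, abs=1e-8)

    def test_interval_brackets_truth_typically(self):
        y, prs, cov = make_data(n=800, beta=1.0, resid_sd=4.0, seed=17)
        truth = 100 * 1.0 / (1.0 + 16.0)
        lo, hi = evaluate.bootstrap_pve_ci(y, prs, cov, n_boot=200, seed=18)
        assert lo < truth < hi


class TestStratifiedEvaluation:
    def test_copied_strata_give_identical_fits(self):
        y, prs, cov = make_data(n=400, seed=19)
        df = cov.copy()
        df["y"] = y
        two = pd.concat([df.assign(stratum="s1"), df.assign(stratum="s2")])
        two.index = pd.Index([f"R{i}" for i in range(len(two))])
        prs2 = pd.DataFrame({"prs": np.tile(prs.to_numpy(), 2)}, index=two.index)
        res = evaluate.stratified_evaluation(
            two, prs2, ["age", "sex"], ["stratum"], traits=("y",), min_n=10
        )
        assert len(res) == 2
        assert res.iloc[0]["beta"] == pytest.approx(res.iloc[1]["beta"], abs=1e-12)
        assert res.iloc[0]["pve"] == pytest.approx(res.iloc[1]["pve"], abs=1e-12)

    def test_known_effect_heterogeneity_recovered(self):
        rng = np.random.default_rng(20)
        n = 10_000
        idx = pd.Index([f"I{i}" for i in range(n)])
        strat = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        prs = pd.Series(rng.standard_normal(n), index=idx)
        beta = np.where(strat == "A", 3.0, 1.0)
        df = pd.DataFrame({"stratum": strat, "age": rng.uniform(20, 80, n)}, index=idx)
        df["y"] = beta * prs + 0.1 * df["age"] + rng.standard_normal(n) * 4
        res = evaluate.stratified_evaluation(
            df, prs.to_frame("prs"), ["age"], ["stratum"], traits=("y",), min_n=10
        ).set_index("stratum")
        assert res.loc["A", "beta"] > res.loc["B", "beta"]

    def test_whole_cohort_equals_single_stratum(self):
        y, prs, cov = make_data(n=300, seed=21)
        df = cov.copy()
        df["y"] = y
        res_all = evaluate.stratified_evaluation(
            df, prs.to_frame("prs"), ["age", "sex"], ["all"], traits=("y",), min_n=10
        )
        fit = evaluate.fit_association(y, prs, cov)
        assert res_all.iloc[0]["beta"] == pytest.approx(fit.beta_prs, abs=1e-12)

    def test_small_stratum_skipped(self):
        y, prs, cov = make_data(n=60, seed=22)
        df = cov.copy()
        df["y"] = y
        df["stratum"] = ["big"] * 55 + ["tiny"] * 5
        res = evaluate.stratified_evaluation(
            df, prs.to_frame("prs"), ["age"], ["stratum"], traits=("y",), min_n=50
        )
        assert list(res["stratum"]) == ["big"]


class TestAuc:
    def test_perfect_separation(self):
        y = np.array([0, 0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        assert evaluate.compute_auc(y, s) == 1.0

    def test_independent_score_near_half(self):
        rng = np.random.default_rng(23)
        y = rng.integers(0, 2, 5000)
        s = rng.standard_normal(5000)
        assert abs(evaluate.compute_auc(y, s) - 0.5) < 0.02

    def test_toy_set_with_tie_matches_enumeration(self):
        y = np.array([1, 0, 1, 0, 1, 0])
        s = np.array([3.0, 1.0, 2.0, 2.0, 0.5, 0.5])
        assert evaluate.compute_auc(y, s) == pytest.approx(pair_counting_auc(y, s))

    def test_matches_sklearn_on_random_data(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(24)
        y = rng.integers(0, 2, 300)
        s = rng.normal(size=300) + y
        assert evaluate.compute_auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            evaluate.compute_auc(np.ones(5), np.arange(5.0))
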