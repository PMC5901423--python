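"""REML heterogeneity estimation and Kenward-Roger small-sample inference."""

import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gaussmeta as gm
from gaussmeta.data import AggregateDataset


def _agg(betas, vs):
    return AggregateDataset(
        pd.DataFrame({"study": [f"s{i}" for i in range(len(betas))],
                      "beta": betas, "se": np.sqrt(vs)})
    )


def _random_agg(seed):
    rng = np.random.default_rng(seed)
    I = int(rng.integers(3, 15))
    v = rng.uniform(0.05, 2.0, I)
    tau2 = rng.uniform(0.0, 3.0)
    b = rng.normal(0.5, np.sqrt(tau2 + v))
    return _agg(b, v)


def grid_argmax_tau2(agg, width=1e-4):
    """Independent grid-search oracle for the REML maximiser (vectorised)."""
    b, v = agg.beta_hats, agg.v
    hi = 10.0 * (np.var(b, ddof=1) + v.max())
    grid = np.arange(0.0, hi, width)
    g = grid[:, None] + v[None, :]
    u = 1.0 / g
    U = u.sum(axis=1)
    bt = (u * b).sum(axis=1) / U
    ll = -0.5 * (np.log(g).sum(axis=1) + np.log(U)
                 + (u * (b - bt[:, None]) ** 2).sum(axis=1))
    return float(grid[np.argmax(ll)])


class TestTwoStageREML:
    def test_no_heterogeneity(self):
        agg = _agg([1.0, 1.0, 1.0, 1.0], [0.5, 0.2, 0.3, 0.4])
        assert gm.reml_tau2(agg) == 0.0

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_balanced_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        I, v = int(rng.integers(4, 12)), float(rng.uniform(0.05, 0.5))
        b = rng.normal(0, 1.2, I)
        agg = _agg(b, np.full(I, v))
        S2 = np.var(b, ddof=1)
        assert gm.reml_tau2(agg) == pytest.approx(max(0.0, S2 - v), abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_grid_search_oracle(self, seed):
        agg = _random_agg(seed)
        assert gm.reml_tau2(agg) == pytest.approx(grid_argmax_tau2(agg), abs=1e-4)

    def test_matches_metafor_reml(self, tmp_path):
        """Cross-check tau2, beta and its naive SE against R metafor."""
        agg = _random_agg(42)
        csv = tmp_path / "agg.csv"
        agg.frame[["beta", "se"]].to_csv(csv, index=False)
        script = (
            f"d <- read.csv('{csv}');"
            "suppressMessages(library(metafor));"
            "f <- rma(yi=d$beta, sei=d$se, method='REML',"
            "         control=list(threshold=1e-10));"
            "cat(sprintf('%.10f %.10f %.10f', f$tau2, f$beta, f$se))"
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        tau2_r, beta_r, se_r = map(float, out.stdout.split())
        fit, _ = gm.fit_two_stage_re(agg)
        assert fit.tau2_hat == pytest.approx(tau2_r, abs=1e-5)
        assert fit.beta_hat == pytest.approx(beta_r, abs=1e-6)
        assert math.sqrt(fit.var_naive) == pytest.approx(se_r, abs=1e-5)


class TestKenwardRogerTwoStage:
    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_balanced_case_is_the_t_interval(self, seed):
        # equal v_i: adjusted variance S^2/I, df I-1, CI = mean +/- t * S/sqrt(I)
        rng = np.random.default_rng(seed)
        I, v = 8, 0.25
        b = rng.normal(1.0, 1.5, I)
        agg = _agg(b, np.full(I, v))
        fit, res = gm.fit_two_stage_re(agg)
        S2 = np.var(b, ddof=1)
        if fit.tau2_hat > 0:  # interior solution: the closed form applies
            assert fit.var_adjusted == pytest.approx(S2 / I, rel=1e-6)
            assert fit.df_kr == pytest.approx(I - 1, abs=1e-6)
            tq = stats.t.ppf(0.975, I - 1)
            assert res.ci_low == pytest.approx(b.mean() - tq * math.sqrt(S2 / I),
                                               abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_adjusted_at_least_naive(self, seed):
        fit, _ = gm.fit_two_stage_re(_random_agg(seed + 20))
        assert fit.var_adjusted >= fit.var_naive

    def test_df_grows_with_studies(self):
        rng = np.random.default_rng(1)
        I = 500
        b = rng.normal(0, 1.0, I)
        fit, res = gm.fit_two_stage_re(_agg(b, np.full(I, 0.3)))
        assert fit.df_kr > 100
        # CI is indistinguishable from the normal-quantile interval
        z = stats.norm.ppf(0.975)
        assert res.ci_high - res.ci_low == pytest.approx(
            2 * z * math.sqrt(fit.var_adjusted), rel=1e-2
        )

    def test_boundary_tau2_collapses_to_fixed_effect(self):
        agg = _agg([1.0, 1.01, 0.99, 1.0], [0.5, 0.2, 0.3, 0.4])
        fit, _ = gm.fit_two_stage_re(agg)
        assert fit.tau2_hat == 0.0
        fe = gm.pool_inverse_variance(agg)
        assert fit.beta_hat == pytest.approx(fe.beta_hat, abs=1e-12)
        assert fit.var_adjusted >= fe.var_hat

    def test_study_order_invariance(self):
        agg = _random_agg(31)
        fit1, _ = gm.fit_two_stage_re(agg)
        perm = agg.frame.sample(frac=1.0, random_state=2).reset_index(drop=True)
        fit2, _ = gm.fit_two_stage_re(AggregateDataset(perm))
        assert fit1.tau2_hat == pytest.approx(fit2.tau2_hat, abs=1e-10)
        assert fit1.df_kr == pytest.approx(fit2.df_kr, rel=1e-8)


class TestOneStageREML:
    def test_optimum_dominates_two_stage_plugin(self, sim_bundle):
        f2, _ = gm.fit_two_stage_re(sim_bundle.ipd)
        f1, _ = gm.fit_one_stage_re(sim_bundle.ipd)
        s = gm.summarize_studies(sim_bundle.ipd)
        ll_plug = gm.one_stage_restricted_loglik(
            sim_bundle.ipd, f2.tau2_hat, np.array([x.sigma2_hat for x in s])
        )
        assert f1.loglik >= ll_plug - 1e-9
        assert f1.converged

    @pytest.mark.parametrize("seed", range(6))
    def test_point_estimates_near_two_stage(self, seed):
        bundle = gm.simulate_meta_ipd(gm.DGMConfig(I=10, seed=seed + 7))
        f1, _ = gm.fit_one_stage_re(bundle.ipd)
        f2, _ = gm.fit_two_stage_re(bundle.ipd)
        scale = abs(f2.beta_hat) + math.sqrt(f2.var_naive)
        assert abs(f1.beta_hat - f2.beta_hat) / scale < 1e-2

    def test_typical_agreement_to_fourth_decimal(self):
        # median relative discrepancy across datasets is tiny
        rel = []
        for seed in range(10):
            bundle = gm.simulate_meta_ipd(gm.DGMConfig(I=10, seed=100 + seed))
            f1, _ = gm.fit_one_stage_re(bundle.ipd)
            f2, _ = gm.fit_two_stage_re(bundle.ipd)
            rel.append(abs(f1.beta_hat - f2.beta_hat)
                       / (abs(f2.beta_hat) + math.sqrt(f2.var_naive)))
        assert np.median(rel) < 1e-3

    def test_constrained_fit_collapses_to_ols(self, sim_bundle):
        fit, _ = gm.fit_one_stage_re(sim_bundle.ipd, shared_sigma2=True,
                                     fix_tau2=0.0)
        ols = gm.fit_one_stage(sim_bundle.ipd, "II", "shared")
        assert fit.beta_hat == pytest.approx(ols.beta_hat, abs=1e-8)
        # REML shared variance equals the unbiased OLS residual mean square,
        # so the model-based variance of beta matches the OLS one
        assert fit.var_naive == pytest.approx(ols.var_hat, rel=1e-6)

    def test_one_stage_df_direction(self):
        # one-stage KR df tend to sit slightly above the two-stage df
        higher = 0
        for seed in range(10):
            bundle = gm.simulate_meta_ipd(gm.DGMConfig(I=8, seed=300 + seed))
            f1, _ = gm.fit_one_stage_re(bundle.ipd)
            f2, _ = gm.fit_two_stage_re(bundle.ipd)
            higher += f1.df_kr > f2.df_kr
        assert higher >= 6

    def test_tau2_invariant_to_shifting_one_study(self, sim_bundle):
        ipd = sim_bundle.ipd
        f0, _ = gm.fit_one_stage_re(ipd)
        target = ipd.study_ids[0]
        y = ipd.y + np.where(ipd.study == target, 25.0, 0.0)
        f1, _ = gm.fit_one_stage_re(gm.IPDDataset(ipd.study, y, ipd.x))
        assert f1.tau2_hat == pytest.approx(f0.tau2_hat, abs=1e-6)
        t2_0 = gm.reml_tau2(ipd)
        t2_1 = gm.reml_tau2(gm.IPDDataset(ipd.study, y, ipd.x))
        assert t2_1 == pytest.approx(t2_0, abs=1e-6)
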