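"""Fixed-effect pooling, one-stage fits and the two variance formulas."""

import math

import numpy as np
import pandas as pd
import pytest

import gaussmeta as gm
from gaussmeta.data import AggregateDataset
from gaussmeta.errors import DegenerateStudyError, UnsupportedModelError

from conftest import random_fixture


def _agg(betas, vs):
    return AggregateDataset(
        pd.DataFrame({"study": [f"s{i}" for i in range(len(betas))],
                      "beta": betas, "se": np.sqrt(vs)})
    )


class TestInverseVariancePooling:
    def test_single_study_identity(self):
        res = gm.pool_inverse_variance(_agg([1.7], [0.3]))
        assert res.beta_hat == pytest.approx(1.7)
        assert res.var_hat == pytest.approx(0.3)

    def test_equal_weights(self):
        res = gm.pool_inverse_variance(_agg([0.0, 2.0], [1.0, 1.0]))
        assert res.beta_hat == pytest.approx(1.0)
        assert res.var_hat == pytest.approx(0.5)

    def test_hand_weighted_mean(self):
        # beta (0, 3), v (1, 2): weighted mean 1, variance 2/3
        res = gm.pool_inverse_variance(_agg([0.0, 3.0], [1.0, 2.0]))
        assert res.beta_hat == pytest.approx(1.0)
        assert res.var_hat == pytest.approx(2.0 / 3.0)

    def test_zero_variance_study_rejected(self):
        bundle = gm.make_toy_fixture([(10, 1.0, 0.0), (10, 0.0, 1.0)], seed=0)
        with pytest.raises(DegenerateStudyError):
            gm.pool_inverse_variance(gm.summarize_studies(bundle.ipd))

    def test_ci_brackets_estimate(self):
        res = gm.pool_inverse_variance(_agg([0.0, 3.0], [1.0, 2.0]), level=0.8)
        assert res.ci_low < res.beta_hat < res.ci_high


class TestOneTwoStageEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_study_specific_identity(self, seed):
        """One-stage weighted fit equals two-stage inverse-variance pooling."""
        bundle = random_fixture(seed)
        one = gm.fit_one_stage(bundle.ipd, "II", "study_specific")
        two = gm.pool_inverse_variance(gm.summarize_studies(bundle.ipd))
        assert abs(one.beta_hat - two.beta_hat) < 1e-10
        assert abs(one.var_hat - two.var_hat) < 1e-10

    @pytest.mark.parametrize("seed", range(12))
    def test_senn_ols_recovery(self, seed):
        """Sample-size-weighted pooling equals the shared-variance OLS fit."""
        bundle = random_fixture(seed + 100)
        one = gm.fit_one_stage(bundle.ipd, "II", "shared")
        two = gm.pool_common_variance(gm.summarize_studies(bundle.ipd))
        assert one.beta_hat == pytest.approx(two.beta_hat, abs=1e-12)
        assert one.var_hat == pytest.approx(two.var_hat, rel=1e-12)
        assert one.df == two.df

    def test_shared_fit_matches_statsmodels(self, toy_bundle):
        import statsmodels.api as sm

        ipd = toy_bundle.ipd
        dummies = pd.get_dummies(pd.Series(ipd.study)).to_numpy(dtype=float)
        X = np.column_stack([dummies, ipd.x])
        fit = sm.OLS(ipd.y, X).fit()
        res = gm.fit_one_stage(ipd, "II", "shared")
        assert res.beta_hat == pytest.approx(fit.params[-1], abs=1e-10)
        assert res.se == pytest.approx(fit.bse[-1], rel=1e-10)

    def test_sample_size_weight_ratio(self):
        # two studies n = 20 and 80 with equal estimates: weights 1:4
        bundle = gm.make_toy_fixture([(20, 1.0, 1.0), (80, 1.0, 1.0)], seed=3)
        s = gm.summarize_studies(bundle.ipd)
        w = [x.n_t * x.n_c / x.n for x in s]
        assert w[1] / w[0] == pytest.approx(4.0)
        res = gm.pool_common_variance(s)
        expect = (w[0] * s[0].beta_hat + w[1] * s[1].beta_hat) / sum(w)
        assert res.beta_hat == pytest.approx(expect, abs=1e-12)


class TestModels:
    def test_model_I_equals_model_II_on_single_study(self):
        bundle = gm.make_toy_fixture([(25, 0.8, 1.3)], seed=6)
        r1 = gm.fit_one_stage(bundle.ipd, "I")
        r2 = gm.fit_one_stage(bundle.ipd, "II", "shared")
        assert r1.beta_hat == pytest.approx(r2.beta_hat, abs=1e-12)
        assert r1.var_hat == pytest.approx(r2.var_hat, rel=1e-12)

    def test_model_IV_per_study_effects(self, toy_bundle):
        res = gm.fit_one_stage(toy_bundle.ipd, "IV")
        assert math.isnan(res.beta_hat)
        per_study = gm.summarize_studies(toy_bundle.ipd)
        for s in per_study:
            assert res.per_study[str(s.study_id)] == pytest.approx(s.beta_hat,
                                                                   abs=1e-10)

    @pytest.mark.parametrize("model", ["I", "IV"])
    def test_study_specific_unsupported(self, model, toy_bundle):
        with pytest.raises(UnsupportedModelError):
            gm.fit_one_stage(toy_bundle.ipd, model, "study_specific")


class TestVarianceFormulas:
    def test_single_study_value(self):
        s = [gm.StudySummary("a", 100, 50, 50, 0.0, 1.0, 1.0 * (1 / 50 + 1 / 50))]
        assert gm.variance_asymptotic(s) == pytest.approx(0.04)

    def test_precision_additivity(self):
        one = [gm.StudySummary("a", 30, 15, 15, 0.0, 2.0, 2.0 * (2 / 15))]
        k = 7
        many = [gm.StudySummary(f"s{i}", 30, 15, 15, 0.0, 2.0, 2.0 * (2 / 15))
                for i in range(k)]
        assert gm.variance_asymptotic(many) == pytest.approx(
            gm.variance_asymptotic(one) / k
        )

    def test_matches_pooled_variance(self, toy_bundle):
        s = gm.summarize_studies(toy_bundle.ipd)
        assert gm.variance_asymptotic(s) == gm.pool_inverse_variance(s).var_hat

    def test_small_sample_single_study_equals_asymptotic(self):
        s = [gm.StudySummary("a", 20, 10, 10, 1.5, 1.0, 0.2)]
        beta = gm.pool_inverse_variance(s).beta_hat
        assert gm.variance_small_sample(s, beta) == pytest.approx(
            gm.variance_asymptotic(s)
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_small_sample_never_below_asymptotic(self, seed):
        bundle = random_fixture(seed + 50)
        s = gm.summarize_studies(bundle.ipd)
        beta = gm.pool_inverse_variance(s).beta_hat
        assert gm.variance_small_sample(s, beta) >= gm.variance_asymptotic(s)

    def test_converges_to_asymptotic_for_huge_studies(self):
        # deviations on the sampling-noise scale sqrt(v), as under a common
        # true effect, so the correction vanishes as n grows
        n = 10**6
        z = [0.3, -1.2, 0.8, 1.9]
        s = [gm.StudySummary(f"s{i}", n, n // 2, n // 2,
                             z[i] * math.sqrt(4.0 / n), 1.0, 1.0 * 4 / n)
             for i in range(4)]
        beta = gm.pool_inverse_variance(s).beta_hat
        va = gm.variance_asymptotic(s)
        vs = gm.variance_small_sample(s, beta)
        assert abs(vs - va) / va < 1e-4


class TestInvariances:
    def test_location_equivariance_and_order_invariance(self):
        bundle = random_fixture(77)
        ipd = bundle.ipd
        res = gm.fit_one_stage(ipd, "II", "study_specific")
        shifted = gm.IPDDataset(study=ipd.study, y=ipd.y + 11.0, x=ipd.x)
        res_shift = gm.fit_one_stage(shifted, "II", "study_specific")
        assert res_shift.beta_hat == pytest.approx(res.beta_hat, abs=1e-9)

        order = np.random.default_rng(0).permutation(ipd.n)
        perm = gm.IPDDataset(study=ipd.study[order], y=ipd.y[order], x=ipd.x[order])
        res_perm = gm.fit_one_stage(perm, "II", "study_specific")
        assert res_perm.beta_hat == pytest.approx(res.beta_hat, abs=1e-10)
        assert res_perm.var_hat == pytest.approx(res.var_hat, rel=1e-10)
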