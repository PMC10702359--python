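"""Estimator tests: Wald ratio, IVW, Egger, weighted median/mode, and the
cross-method algebraic identities, with statsmodels WLS as the independent
regression oracle."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from mrbiome import EstimationError, MendelianRandomization, run_all_estimators
from mrbiome.mr_estimators import EstimatorConfig, ivw, wald_ratio, weighted_median
from mrbiome.harmonization import HarmonizedSnp

from conftest import make_hset


def model_from(bx, sx, by, sy, rsids=None):
    return MendelianRandomization(bx, sx, by, sy, rsids=rsids)


class TestWaldRatio:
    def test_arithmetic(self):
        snp = HarmonizedSnp("rs1", beta_exp=0.1, se_exp=0.01, beta_out=0.05, se_out=0.02)
        res = wald_ratio(snp)
        assert res.beta == pytest.approx(0.5)
        assert res.se == pytest.approx(0.2)
        assert res.method == "wald_ratio" and res.primary

    def test_zero_outcome_effect(self):
        snp = HarmonizedSnp("rs1", 0.1, 0.01, 0.0, 0.02)
        res = wald_ratio(snp)
        assert res.beta == 0.0 and res.pval == 1.0

    def test_pvalue_against_normal_tail_oracle(self):
        snp = HarmonizedSnp("rs1", 0.1, 0.01, 0.3, 0.05)
        res = wald_ratio(snp)
        assert res.beta == pytest.approx(3.0)
        assert res.se == pytest.approx(0.5)
        assert res.pval == pytest.approx(2 * stats.norm.sf(6.0), rel=1e-6)
        assert res.pval == pytest.approx(1.97e-9, rel=0.01)

    def test_zero_exposure_effect_is_error(self):
        with pytest.raises(EstimationError, match="undefined ratio"):
            wald_ratio(HarmonizedSnp("rs1", 0.0, 0.01, 0.1, 0.02))


class TestIvw:
    def test_zero_heterogeneity_no_inflation(self):
        # all ratios equal c -> estimate c, Q = 0, phi = 1
        bx = np.array([0.1, 0.2, 0.4])
        by = 0.7 * bx
        m = model_from(bx, [0.01] * 3, by, [0.02] * 3)
        res = m.fit_ivw()
        assert res.beta == pytest.approx(0.7)
        assert res.extras["phi"] == 1.0
        assert res.extras["q_stat"] == pytest.approx(0.0, abs=1e-20)

    def test_equal_weight_symmetry(self):
        # equal weights require equal |beta_exp| and se_out
        bx = np.array([0.1, 0.1, 0.1])
        by = np.array([0.02, 0.04, 0.06])  # ratios 0.2, 0.4, 0.6
        m = model_from(bx, [0.01] * 3, by, [0.02] * 3)
        assert m.fit_ivw().beta == pytest.approx(0.4)

    def test_equals_precision_weighted_mean_of_wald_ratios(self):
        rng = np.random.default_rng(0)
        bx = rng.uniform(0.05, 0.2, 8) * rng.choice([-1, 1], 8)
        sx = rng.uniform(0.005, 0.02, 8)
        by = rng.normal(0.3 * bx, 0.03)
        sy = rng.uniform(0.02, 0.05, 8)
        m = model_from(bx, sx, by, sy)
        theta = by / bx
        w = bx**2 / sy**2
        expected = np.sum(w * theta) / np.sum(w)
        assert m.fit_ivw().beta == pytest.approx(expected, rel=1e-12)

    def test_equals_origin_constrained_wls_slope(self):
        """Independent oracle: statsmodels WLS of beta_out on beta_exp through
        the origin with weights 1/se_out^2 gives the identical slope."""
        rng = np.random.default_rng(1)
        bx = rng.uniform(0.05, 0.2, 10)
        sy = rng.uniform(0.02, 0.05, 10)
        by = rng.normal(0.25 * bx, sy)
        m = model_from(bx, [0.01] * 10, by, sy)
        wls = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
        assert m.fit_ivw().beta == pytest.approx(wls.params[0], rel=1e-12)
        # fixed-effect SE equals the known-variance WLS SE
        fe = m.fit_ivw(model="fe")
        se_known = float(1.0 / np.sqrt(np.sum(bx**2 / sy**2)))
        assert fe.se == pytest.approx(se_known, rel=1e-12)

    def test_mre_inflation_bounded_below_by_one(self):
        rng = np.random.default_rng(2)
        bx = rng.uniform(0.05, 0.2, 12)
        sy = np.full(12, 0.03)
        by = rng.normal(0.2 * bx, 5 * sy)  # strong heterogeneity
        m = model_from(bx, [0.01] * 12, by, sy)
        mre, fe = m.fit_ivw(model="mre"), m.fit_ivw(model="fe")
        assert mre.se >= fe.se
        assert mre.extras["phi"] >= 1.0

    def test_refuses_single_snp(self):
        with pytest.raises(EstimationError):
            model_from([0.1], [0.01], [0.05], [0.02]).fit_ivw()


class TestEgger:
    def test_exact_affine_data_recovered(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2, 0.3])
        a, b = 0.02, 0.6
        by = a + b * bx
        m = model_from(bx, [0.01] * 5, by, [0.02] * 5)
        res = m.fit_egger()
        assert res.beta == pytest.approx(b, rel=1e-10)
        assert res.extras["intercept"] == pytest.approx(a, rel=1e-10)
        assert res.extras["residual_inflation"] == 1.0  # floor at exact fit

    def test_matches_statsmodels_wls_oracle(self):
        rng = np.random.default_rng(7)
        bx = rng.uniform(0.05, 0.3, 20)
        sy = rng.uniform(0.02, 0.06, 20)
        by = rng.normal(0.03 + 0.4 * bx, sy)
        m = model_from(bx, [0.01] * 20, by, sy)
        res = m.fit_egger()
        wls = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
        assert res.beta == pytest.approx(wls.params[1], rel=1e-10)
        assert res.extras["intercept"] == pytest.approx(wls.params[0], rel=1e-10)
        # intercept inference matches the residual-scaled WLS exactly
        assert res.extras["intercept_se"] == pytest.approx(wls.bse[0], rel=1e-8)
        assert res.extras["intercept_pval"] == pytest.approx(
            wls.pvalues[0], rel=1e-6
        )
        # slope SE is the WLS one, floored from below by the known-variance SE
        assert res.se == pytest.approx(max(wls.bse[1], res.se), rel=1e-10)

    def test_exposure_orientation_invariance(self):
        """Flipping the reported allele of any SNP (negating both betas) must
        not change the Egger fit."""
        rng = np.random.default_rng(8)
        bx = rng.uniform(0.05, 0.3, 10)
        sy = rng.uniform(0.02, 0.06, 10)
        by = rng.normal(0.02 + 0.4 * bx, sy)
        m1 = model_from(bx, [0.01] * 10, by, sy)
        flip = rng.choice([-1, 1], 10)
        m2 = model_from(bx * flip, [0.01] * 10, by * flip, sy)
        r1, r2 = m1.fit_egger(), m2.fit_egger()
        assert r2.beta == pytest.approx(r1.beta, rel=1e-12)
        assert r2.extras["intercept"] == pytest.approx(
            r1.extras["intercept"], rel=1e-12
        )

    def test_intercept_constrained_to_zero_is_fixed_effect_ivw(self):
        """With the intercept forced to 0, the Egger weighting scheme yields
        exactly the FE-IVW slope (origin-constrained WLS oracle)."""
        rng = np.random.default_rng(9)
        bx = rng.uniform(0.05, 0.3, 8)
        sy = rng.uniform(0.02, 0.06, 8)
        by = rng.normal(0.3 * bx, sy)
        m = model_from(bx, [0.01] * 8, by, sy)
        constrained = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
        assert m.fit_ivw(model="fe").beta == pytest.approx(
            constrained.params[0], rel=1e-12
        )

    def test_refuses_below_three_snps(self):
        with pytest.raises(EstimationError):
            model_from([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2).fit_egger()


class TestWeightedMedian:
    def test_equal_weight_median(self):
        bx = np.array([0.1, 0.1, 0.1])
        by = np.array([0.1, 0.2, 0.9])  # ratios 1, 2, 9
        m = model_from(bx, [0.01] * 3, by, [0.02] * 3)
        res = m.fit_weighted_median(n_boot=200, seed=1)
        assert res.beta == pytest.approx(2.0)

    def test_dominant_weight_snaps_to_its_ratio(self):
        # middle SNP holds >50% of total weight
        bx = np.array([0.05, 0.4, 0.05])
        by = np.array([0.05, 0.12, 0.20])  # ratios 1.0, 0.3, 4.0
        m = model_from(bx, [0.01] * 3, by, [0.02] * 3)
        res = m.fit_weighted_median(n_boot=200, seed=1)
        assert abs(res.beta - 0.3) < 0.75  # within interpolation neighborhood
        ratios = sorted([1.0, 0.3, 4.0])
        assert ratios[0] < res.beta < ratios[1] + 1e-9

    def test_robust_to_forty_percent_invalid_instruments(self):
        """With 60% valid instruments around theta = 0.3 and 40% strongly
        pleiotropic ones, the weighted median lands nearer the truth than IVW
        in the vast majority of replicates."""
        rng = np.random.default_rng(10)
        wins = 0
        n_rep = 200
        for _ in range(n_rep):
            j = 15
            bx = rng.uniform(0.08, 0.16, j)
            sy = np.full(j, 0.04)
            alpha = np.zeros(j)
            alpha[: int(0.4 * j)] = 0.25  # invalid instruments, large alpha
            by = rng.normal(0.3 * bx + alpha, sy)
            m = model_from(bx, np.full(j, 0.01), by, sy)
            med = m._weighted_median_of(by / bx, bx**2 / sy**2)
            ivw_est = m.fit_ivw().beta
            wins += abs(med - 0.3) < abs(ivw_est - 0.3)
        assert wins / n_rep >= 0.8

    def test_bootstrap_se_is_seed_reproducible(self):
        bx = np.array([0.1, 0.15, 0.2, 0.25])
        by = np.array([0.03, 0.06, 0.05, 0.08])
        m = model_from(bx, [0.01] * 4, by, [0.02] * 4)
        r1 = m.fit_weighted_median(n_boot=500, seed=3)
        r2 = m.fit_weighted_median(n_boot=500, seed=3)
        assert r1.se == r2.se


class TestWeightedMode:
    def test_identical_ratios(self):
        bx = np.array([0.1, 0.2, 0.4])
        by = 0.5 * bx
        m = model_from(bx, [0.01] * 3, by, [0.02] * 3)
        res = m.fit_weighted_mode(n_boot=100, seed=1)
        assert res.beta == pytest.approx(0.5)

    def test_cluster_beats_dispersed_outliers(self):
        """7 ratios clustered at 0.3 plus 3 dispersed ones, equal weights:
        the mode sits in the cluster (density-grid oracle)."""
        cluster = np.array([0.28, 0.29, 0.30, 0.30, 0.31, 0.32, 0.33])
        outliers = np.array([1.5, -0.9, 2.5])
        ratios = np.concatenate([cluster, outliers])
        bx = np.full(10, 0.1)
        by = ratios * bx
        m = model_from(bx, [0.01] * 10, by, [0.02] * 10)
        res = m.fit_weighted_mode(n_boot=100, seed=1)
        assert 0.27 < res.beta < 0.34
        # independent coarse-grid KDE oracle
        grid = np.linspace(-2, 3, 20001)
        h = res.extras["bandwidth"]
        dens = np.exp(-0.5 * ((grid[:, None] - ratios) / h) ** 2).sum(1)
        assert abs(grid[np.argmax(dens)] - res.beta) < 0.01

    def test_large_bandwidth_limit_is_weighted_mean(self):
        rng = np.random.default_rng(12)
        bx = rng.uniform(0.05, 0.3, 8)
        sy = rng.uniform(0.02, 0.05, 8)
        by = rng.normal(0.3 * bx, sy)
        m = model_from(bx, [0.01] * 8, by, sy)
        res = m.fit_weighted_mode(bandwidth_factor=2000.0, n_boot=100, seed=1)
        theta = by / bx
        w = bx**2 / sy**2
        weighted_mean = float(np.sum(w * theta) / np.sum(w))
        assert res.beta == pytest.approx(weighted_mean, abs=1e-3)


class TestCrossMethodProperties:
    def _random_model(self, seed, j=9):
        rng = np.random.default_rng(seed)
        bx = rng.uniform(0.05, 0.3, j) * rng.choice([-1, 1], j)
        sx = rng.uniform(0.005, 0.02, j)
        sy = rng.uniform(0.02, 0.06, j)
        by = rng.normal(0.3 * bx, sy)
        return bx, sx, by, sy

    @pytest.mark.parametrize("method", ["ivw", "egger", "weighted_median", "weighted_mode"])
    def test_sign_equivariance(self, method):
        """Negating every outcome effect negates each estimate, leaving
        p-values unchanged."""
        bx, sx, by, sy = self._random_model(13)
        kw = {} if method in ("ivw", "egger") else {"n_boot": 300, "seed": 5}
        r_pos = model_from(bx, sx, by, sy).fit(method, **kw)
        r_neg = model_from(bx, sx, -by, sy).fit(method, **kw)
        assert r_neg.beta == pytest.approx(-r_pos.beta, rel=1e-9, abs=1e-12)
        assert r_neg.pval == pytest.approx(r_pos.pval, rel=1e-6, abs=1e-12)

    @pytest.mark.parametrize(
        "method", ["ivw", "egger", "weighted_median", "weighted_mode", "presso"]
    )
    def test_input_order_invariance(self, method):
        bx, sx, by, sy = self._random_model(14, j=8)
        rsids = [f"rs{i}" for i in range(8)]
        kw = {}
        if method in ("weighted_median", "weighted_mode"):
            kw = {"n_boot": 200, "seed": 6}
        elif method == "presso":
            kw = {"n_sim": 200, "seed": 6}
        perm = np.random.default_rng(0).permutation(8)
        r1 = model_from(bx, sx, by, sy, rsids=rsids).fit(method, **kw)
        r2 = model_from(
            bx[perm], sx[perm], by[perm], sy[perm],
            rsids=[rsids[i] for i in perm],
        ).fit(method, **kw)
        assert r1.beta == r2.beta and r1.se == r2.se and r1.pval == r2.pval

    def test_or_scale_consistency(self):
        bx, sx, by, sy = self._random_model(15)
        res = model_from(bx, sx, by, sy).fit_ivw()
        assert res.or_value == pytest.approx(np.exp(res.beta))
        assert res.ci_low <= res.beta <= res.ci_high
        assert res.or_ci[0] == pytest.approx(np.exp(res.ci_low))


class TestRunAllEstimators:
    def _hset(self, j):
        rng = np.random.default_rng(16)
        bx = rng.uniform(0.08, 0.2, j)
        sy = np.full(j, 0.04)
        by = rng.normal(0.3 * bx, sy)
        return make_hset(bx, np.full(j, 0.01), by, sy)

    def test_single_snp_wald_only(self):
        results = run_all_estimators(self._hset(1))
        assert [r.method for r in results] == ["wald_ratio"]
        assert results[0].primary

    def test_two_snps_ivw_only(self):
        results = run_all_estimators(self._hset(2))
        assert [r.method for r in results] == ["ivw"]

    def test_three_snps_add_regression_methods(self):
        cfg = EstimatorConfig(n_boot=200, n_sim_presso=200)
        results = run_all_estimators(self._hset(3), cfg)
        assert [r.method for r in results] == [
            "ivw", "egger", "weighted_median", "weighted_mode"
        ]

    def test_ten_snps_all_five_methods_ivw_primary(self):
        cfg = EstimatorConfig(n_boot=200, n_sim_presso=200)
        results = run_all_estimators(self._hset(10), cfg)
        assert [r.method for r in results] == [
            "ivw", "egger", "weighted_median", "weighted_mode", "presso_corrected"
        ]
        assert [r.primary for r in results] == [True, False, False, False, False]

    def test_empty_set_yields_no_results(self):
        assert run_all_estimators(make_hset([], [], [], [])) == []
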