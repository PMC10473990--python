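"""Unit and property tests for the quantile-regression process stage."""

import numpy as np
import pytest
from scipy.stats import norm

from quantgwas import (
    DEFAULT_TAU_GRID, QuantileFit, QuantileProfile, check_loss,
    delta_r2_profile, fit_quantile, linear_effect, quantile_process, r1_adj,
    sparsity_estimate, wald_heteroscedasticity,
)
from conftest import brute_force_check_loss


@pytest.mark.parametrize("u, tau, expected", [
    (2.0, 0.85, 1.7),
    (-2.0, 0.85, 0.3),
    (0.0, 0.5, 0.0),
    (0.0, 0.05, 0.0),
])
def test_check_loss_values(u, tau, expected):
    assert check_loss(u, tau) == pytest.approx(expected)


def test_check_loss_rejects_bad_tau():
    with pytest.raises(ValueError):
        check_loss(1.0, 0.0)
    with pytest.raises(ValueError):
        check_loss(1.0, 1.0)


class TestFitQuantile:
    def test_intercept_only_median(self):
        fit = fit_quantile([1, 2, 3, 4, 5], np.ones((5, 1)), 0.5)
        assert fit.coefficients[0] == pytest.approx(3.0)

    def test_intercept_only_lower_quartile_unique(self):
        # objective at c=2 is 2.25, the unique minimiser
        fit = fit_quantile([1, 2, 3, 4, 5], np.ones((5, 1)), 0.25)
        assert fit.coefficients[0] == pytest.approx(2.0)
        assert fit.objective == pytest.approx(2.25)

    def test_intercept_only_equals_type1_quantile(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(37)
        for tau in (0.1, 0.25, 0.5, 0.8, 0.95):
            fit = fit_quantile(y, np.ones((37, 1)), tau)
            k = int(np.ceil(37 * tau))
            assert fit.coefficients[0] == pytest.approx(np.sort(y)[k - 1])

    def test_objective_matches_residual_loss(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(40), rng.standard_normal(40)])
        y = X @ [1.0, 0.5] + rng.standard_normal(40)
        fit = fit_quantile(y, X, 0.3)
        assert fit.objective == pytest.approx(
            float(np.sum(check_loss(fit.residuals, 0.3))), rel=1e-9)

    def test_basic_solution_optimality_condition(self):
        # count(residual<0) <= n*tau and count(residual<=0) >= n*tau - p
        rng = np.random.default_rng(8)
        n, p = 200, 3
        X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
        y = X @ rng.standard_normal(p) + rng.standard_normal(n)
        for tau in (0.1, 0.5, 0.9):
            fit = fit_quantile(y, X, tau)
            neg = int(np.sum(fit.residuals < -1e-10))
            nonpos = int(np.sum(fit.residuals <= 1e-10))
            assert neg <= n * tau + 1e-9
            assert nonpos >= n * tau - p - 1e-9

    def test_matches_enumeration_oracle_small(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            n = int(rng.integers(4, 13))
            p = int(rng.integers(1, 3))
            X = rng.standard_normal((n, p))
            X[:, 0] = 1.0
            y = rng.standard_normal(n)
            tau = float(rng.uniform(0.05, 0.95))
            fit = fit_quantile(y, X, tau)
            oracle = brute_force_check_loss(y, X, tau)
            assert fit.objective == pytest.approx(oracle, rel=1e-8, abs=1e-10)

    def test_matches_statsmodels_quantreg(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(9)
        n = 300
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [1.0, 0.4] + rng.standard_normal(n)
        for tau in (0.25, 0.5, 0.8):
            ours = fit_quantile(y, X, tau)
            theirs = sm.QuantReg(y, X).fit(q=tau)
            their_obj = float(np.sum(check_loss(y - X @ theirs.params, tau)))
            # our LP optimum can only be at least as good
            assert ours.objective <= their_obj + 1e-6
            assert np.allclose(ours.coefficients, theirs.params, atol=5e-3)

    def test_rank_deficient_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="rank"):
            fit_quantile(np.arange(10.0), X, 0.5)


class TestEquivariance:
    def test_scale_equivariance(self):
        rng = np.random.default_rng(12)
        n = 80
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [2.0, 1.0] + rng.standard_normal(n)
        f1 = fit_quantile(y, X, 0.3)
        f2 = fit_quantile(3.5 * y, X, 0.3)
        assert np.allclose(f2.coefficients, 3.5 * f1.coefficients, atol=1e-8)
        assert f2.objective == pytest.approx(3.5 * f1.objective, rel=1e-8)

    def test_regression_shift_equivariance(self):
        rng = np.random.default_rng(13)
        n = 80
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        delta = np.array([1.5, -0.7])
        f1 = fit_quantile(y, X, 0.7)
        f2 = fit_quantile(y + X @ delta, X, 0.7)
        assert np.allclose(f2.coefficients, f1.coefficients + delta, atol=1e-8)
        assert f2.objective == pytest.approx(f1.objective, rel=1e-8)


class TestSparsity:
    def test_normal_residuals_density_reciprocal(self):
        rng = np.random.default_rng(4)
        fit = QuantileFit(0.5, np.zeros(1), 0.0, rng.standard_normal(5000))
        s = sparsity_estimate(fit, 5000)
        assert s == pytest.approx(np.sqrt(2 * np.pi), rel=0.10)

    def test_uniform_residuals_unit_density(self):
        rng = np.random.default_rng(6)
        fit = QuantileFit(0.5, np.zeros(1), 0.0, rng.uniform(0, 1, 5000))
        assert sparsity_estimate(fit, 5000) == pytest.approx(1.0, rel=0.10)

    def test_tail_bandwidth_clamped(self):
        rng = np.random.default_rng(7)
        fit = QuantileFit(0.05, np.zeros(1), 0.0, rng.standard_normal(60))
        sparsity_estimate(fit, 60)
        assert fit.sparsity_clamped

    def test_too_small_sample_errors(self):
        fit = QuantileFit(0.5, np.zeros(1), 0.0, np.arange(2.0))
        with pytest.raises(ValueError):
            sparsity_estimate(fit, 1)


class TestQuantileProcess:
    def test_default_grid_has_19_fits(self, small_cohort):
        cohort, geno, _ = small_cohort
        y = np.log(cohort["insulin_pmol_l"].to_numpy())
        X = np.column_stack([np.ones(len(y)), geno.column("loc1")])
        prof = quantile_process(y, X, snp_column=1, snp_id="loc1")
        assert len(prof.tau_grid) == 19
        assert prof.beta_path.shape == (19,)
        assert np.allclose(prof.tau_grid, DEFAULT_TAU_GRID)

    def test_process_cov_diagonal_consistency(self, small_cohort):
        cohort, geno, _ = small_cohort
        y = np.log(cohort["insulin_pmol_l"].to_numpy())
        X = np.column_stack([np.ones(len(y)), geno.column("loc1")])
        prof = quantile_process(y, X, snp_column=1)
        v_gg = np.linalg.inv(X.T @ X)[1, 1]
        expected = (prof.tau_grid * (1 - prof.tau_grid)
                    * prof.sparsities**2 * v_gg)
        assert np.allclose(np.diag(prof.process_cov), expected)
        # symmetric positive semidefinite
        assert np.allclose(prof.process_cov, prof.process_cov.T)
        assert np.all(np.linalg.eigvalsh(prof.process_cov) > -1e-12)

    def test_grid_validation(self):
        y = np.random.default_rng(0).standard_normal(50)
        X = np.ones((50, 1))
        with pytest.raises(ValueError):
            quantile_process(y, X, tau_grid=[0.5, 0.3])

    def test_location_scale_slope_recovery(self):
        # fitted path regressed on Phi^{-1}(tau) recovers gamma*sigma
        rng = np.random.default_rng(21)
        n = 5000
        g = rng.binomial(2, 0.3, n).astype(float)
        gam_sig = 0.2 * 0.5
        y = 1.0 + 0.05 * g + (1 + 0.2 * g) * 0.5 * rng.standard_normal(n)
        X = np.column_stack([np.ones(n), g])
        prof = quantile_process(y, X, snp_column=1)
        zq = norm.ppf(prof.tau_grid)
        slope = np.polyfit(zq, prof.beta_path, 1)[0]
        assert slope == pytest.approx(gam_sig, rel=0.25)


class TestWaldHeteroscedasticity:
    def _profile(self, beta, cov):
        m = len(beta)
        return QuantileProfile("s", DEFAULT_TAU_GRID[:m], np.asarray(beta),
                               np.sqrt(np.diag(cov)), beta, beta,
                               np.asarray(cov), np.zeros(m), np.ones(m))

    def test_flat_path_gives_w_zero_p_one(self):
        m = 19
        cov = 0.01 * np.eye(m) + 0.005
        w, df, p = wald_heteroscedasticity(self._profile(np.full(m, 0.3), cov))
        assert w == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert df == m - 1

    def test_zero_rank_errors(self):
        with pytest.raises(ValueError):
            wald_heteroscedasticity(
                self._profile(np.arange(5.0), np.zeros((5, 5))))

    def test_varying_path_rejected(self, small_cohort):
        cohort, geno, truth = small_cohort
        rng = np.random.default_rng(30)
        n = 3000
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 1.0 + (1 + 0.25 * g) * 0.6 * rng.standard_normal(n)
        prof = quantile_process(y, np.column_stack([np.ones(n), g]),
                                snp_column=1)
        assert prof.hs_p < 0.002


class TestR1:
    def test_equal_losses_zero(self):
        assert r1_adj(5.0, 5.0, 100, 3, 3).adjusted == 0.0

    def test_perfect_fit_one(self):
        assert r1_adj(0.0, 5.0, 100, 3, 1).raw == 1.0
        assert r1_adj(0.0, 5.0, 100, 3, 1).adjusted == 1.0

    def test_exact_line_raw_r1(self):
        y = np.array([1.0, 2, 3, 4, 5])
        x = np.array([1.0, 2, 3, 4, 5])
        v_r = fit_quantile(y, np.ones((5, 1)), 0.5).objective
        v_f = fit_quantile(y, np.column_stack([np.ones(5), x]), 0.5).objective
        assert r1_adj(v_f, v_r, 5, 2, 1).raw == pytest.approx(1.0)

    def test_non_nested_evidence_errors(self):
        with pytest.raises(ValueError):
            r1_adj(1.0, 0.0, 100, 3, 1)

    def test_adjustment_floor(self):
        res = r1_adj(4.999, 5.0, 20, 10, 1)
        assert res.adjusted >= 0.0


class TestDeltaR2:
    def test_empty_set_is_zero(self, small_cohort):
        cohort, geno, _ = small_cohort
        y = np.log(cohort["insulin_pmol_l"].to_numpy())
        X = np.column_stack([np.ones(len(y)), cohort["age_years"]])
        deltas = delta_r2_profile(y, X, geno.dosages, {"empty": []},
                                  tau_grid=[0.25, 0.5, 0.75])
        assert np.allclose(deltas["empty"], 0.0)

    def test_duplicate_column_rejected(self, small_cohort):
        cohort, geno, _ = small_cohort
        y = np.log(cohort["insulin_pmol_l"].to_numpy())
        X = np.ones((len(y), 1))
        with pytest.raises(ValueError):
            delta_r2_profile(y, X, geno.dosages, {"dup": [0, 0]},
                             tau_grid=[0.5])

    def test_noise_snps_tiny_improvement(self):
        rng = np.random.default_rng(17)
        n = 1500
        G = rng.binomial(2, 0.3, (n, 5)).astype(float)
        y = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        deltas = delta_r2_profile(y, X, G, {"noise": [0, 1, 2, 3, 4]},
                                  tau_grid=[0.05, 0.5, 0.95])
        assert np.max(deltas["noise"]) < 0.01


class TestLinearEffect:
    def test_noiseless_exact(self):
        g = np.array([0.0, 1, 2, 0, 1, 2])
        y = 2.0 + 0.5 * g
        X = np.column_stack([np.ones(6), g])
        beta, se, _ = linear_effect(y, X)
        assert beta == pytest.approx(0.5, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-7)

    def test_constant_dosage_errors(self):
        X = np.column_stack([np.ones(10), np.full(10, 2.0)])
        with pytest.raises(ValueError):
            linear_effect(np.arange(10.0), X)

    def test_coverage_sampling(self):
        rng = np.random.default_rng(19)
        cover = 0
        for _ in range(200):
            n = 400
            g = rng.binomial(2, 0.3, n).astype(float)
            y = 0.1 * g + 0.5 * rng.standard_normal(n)
            beta, se, _ = linear_effect(y, np.column_stack([np.ones(n), g]))
            cover += abs(beta - 0.1) <= 2 * se
        assert cover / 200 >= 0.93


class TestAlternativeSeMethods:
    def _data(self, n=400, seed=23):
        rng = np.random.default_rng(seed)
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 1.0 + 0.1 * g + 0.5 * rng.standard_normal(n)
        return y, np.column_stack([np.ones(n), g])

    def test_bootstrap_cov_agrees_with_iid_under_iid_errors(self):
        y, X = self._data()
        iid = quantile_process(y, X, tau_grid=[0.25, 0.5, 0.75], snp_column=1)
        boot = quantile_process(y, X, tau_grid=[0.25, 0.5, 0.75], snp_column=1,
                                se_method="bootstrap", n_boot=150, seed=5)
        assert np.allclose(boot.beta_path, iid.beta_path)
        ratio = boot.se_path / iid.se_path
        assert np.all(ratio > 0.5) and np.all(ratio < 2.0)

    def test_nid_sandwich_close_to_iid_under_iid_errors(self):
        y, X = self._data()
        iid = quantile_process(y, X, tau_grid=[0.25, 0.5, 0.75], snp_column=1)
        nid = quantile_process(y, X, tau_grid=[0.25, 0.5, 0.75], snp_column=1,
                               se_method="nid")
        ratio = nid.se_path / iid.se_path
        assert np.all(ratio > 0.5) and np.all(ratio < 2.0)

    def test_unknown_method_rejected(self):
        y, X = self._data(n=60)
        with pytest.raises(ValueError):
            quantile_process(y, X, tau_grid=[0.5], se_method="magic")
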