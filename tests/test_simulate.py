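"""Synthetic study generator: correlation structure, AFT families, censoring."""

import dataclasses

import numpy as np
import pytest

from carscreen.simulate import (
    SimulationDesign,
    _block_sizes,
    block_correlation_matrix,
    calibrate_censoring,
    calibrate_lognormal_noise,
    calibrate_weibull_shape,
    make_coefficients,
    nearest_correlation,
    scenario_calibration,
    simulate_dataset,
)


class TestBlockCorrelation:
    def test_structure_contract(self):
        d = 99
        C = block_correlation_matrix(d, seed=0)
        np.testing.assert_allclose(np.diag(C), 1.0)
        sizes = _block_sizes(d)
        s = np.cumsum([0] + list(sizes))
        # between-block entries zero
        assert np.abs(C[s[0] : s[1], s[1] : s[2]]).max() == 0.0
        assert np.abs(C[s[0] : s[1], s[2] : s[3]]).max() == 0.0
        # PSD after repair
        assert np.linalg.eigvalsh(C).min() >= -1e-8
        # within-block magnitudes keep their nominal values
        for b, rho in zip(range(3), (0.25, 0.5, 0.75)):
            blk = C[s[b] : s[b + 1], s[b] : s[b + 1]]
            off = blk[~np.eye(sizes[b], dtype=bool)]
            np.testing.assert_allclose(np.abs(off), rho, atol=1e-7)

    def test_sign_balance(self):
        C = block_correlation_matrix(300, seed=3)
        sizes = _block_sizes(300)
        s = np.cumsum([0] + list(sizes))
        for b in range(3):
            blk = C[s[b] : s[b + 1], s[b] : s[b + 1]]
            off = blk[~np.eye(sizes[b], dtype=bool)]
            assert 0.45 < np.mean(off > 0) < 0.55

    def test_too_small_d_rejected(self):
        with pytest.raises(ValueError):
            block_correlation_matrix(4)


class TestNearestCorrelation:
    def test_valid_matrix_is_fixed_point(self, rng):
        A = rng.standard_normal((5, 8))
        C = np.corrcoef(A)
        np.testing.assert_allclose(nearest_correlation(C), C, atol=1e-10)

    def test_psd_two_by_two_unchanged(self):
        C = np.array([[1.0, 0.9], [0.9, 1.0]])
        np.testing.assert_allclose(nearest_correlation(C), C, atol=1e-12)

    def test_indefinite_repair_near_optimal(self):
        A = np.array(
            [[1.0, 0.99, 0.99], [0.99, 1.0, -0.99], [0.99, -0.99, 1.0]]
        )
        R = nearest_correlation(A)
        assert np.linalg.eigvalsh(R).min() >= -1e-8
        np.testing.assert_allclose(np.diag(R), 1.0, atol=1e-12)
        dist = np.linalg.norm(R - A, "fro")
        # coarse grid of symmetric candidate correlation matrices
        grid = np.linspace(-0.99, 0.99, 30)
        for a in grid:
            cand = np.array([[1.0, a, a], [a, 1.0, -a], [a, -a, 1.0]])
            if np.linalg.eigvalsh(cand).min() >= 0:
                assert np.linalg.norm(cand - A, "fro") >= dist - 1e-6

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            nearest_correlation(np.array([[1.0, 0.5], [0.2, 1.0]]))


class TestCoefficients:
    def test_endpoints(self):
        np.testing.assert_allclose(make_coefficients(2), [-0.9, 1.0])

    def test_twenty_has_exact_zero_with_warning(self):
        with pytest.warns(UserWarning, match="exact zero"):
            beta = make_coefficients(20)
        assert beta[9] == pytest.approx(0.0, abs=1e-15)
        np.testing.assert_allclose(np.diff(beta), 0.1)

    def test_single_coefficient_convention(self):
        np.testing.assert_array_equal(make_coefficients(1), [1.0])


class TestNoiseCalibration:
    def test_closed_form(self):
        assert calibrate_lognormal_noise(np.eye(2), [1.0, 0.0], 0.5) == 1.0
        assert calibrate_lognormal_noise(np.eye(2), [1.0, 0.0], 0.75) == pytest.approx(
            1.0 / 3.0
        )

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            calibrate_lognormal_noise(np.eye(2), [0.0, 0.0], 0.5)

    def test_monte_carlo_r_squared(self, rng):
        Sigma = np.array([[1.0, 0.3], [0.3, 1.0]])
        beta = np.array([0.8, -0.4])
        exp_var = 0.5
        s2 = calibrate_lognormal_noise(Sigma, beta, exp_var)
        n = 100_000
        X = rng.multivariate_normal(np.zeros(2), Sigma, n)
        y = X @ beta + rng.normal(0, np.sqrt(s2), n)
        r2 = np.var(X @ beta) / np.var(y)
        assert abs(r2 - exp_var) < 0.01


class TestWeibullCalibration:
    def test_matches_closed_form(self):
        Sigma = np.eye(3)
        beta = np.array([0.5, -0.5, 0.8])
        snr = 0.5
        phi = calibrate_weibull_shape(Sigma, beta, snr, pilot_size=200_000, seed=1)
        closed = np.pi * np.sqrt(snr / (6 * float(beta @ beta)))
        assert phi == pytest.approx(closed, rel=0.02)

    def test_snr_scaling_law(self):
        Sigma = np.eye(2)
        beta = np.array([1.0, 0.0])
        phi1 = calibrate_weibull_shape(Sigma, beta, 0.5, pilot_size=100_000, seed=2)
        phi2 = calibrate_weibull_shape(Sigma, beta, 0.25, pilot_size=100_000, seed=2)
        assert (1 / phi2**2) / (1 / phi1**2) == pytest.approx(2.0, rel=0.05)

    def test_zero_beta_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            calibrate_weibull_shape(np.eye(2), np.zeros(2), 0.5)


class TestCensoringCalibration:
    def _design(self, **kw):
        base = dict(n=500, d=9, rel_var=0.34, cens_rate=0.25, seed=5,
                    pilot_size=50_000)
        base.update(kw)
        return SimulationDesign(**base)

    def test_pilot_rate_hits_target(self):
        des = self._design()
        cal = scenario_calibration(des)
        rng = np.random.default_rng(77)
        _, _, status = cal.draw(rng, 50_000)
        assert 0.23 <= np.mean(status == 0) <= 0.27

    def test_below_admin_floor_rejected(self):
        des = self._design(cens_rate=0.05)
        with pytest.raises(ValueError, match="administrative"):
            scenario_calibration(des)

    def test_admin_cutoff_stable_across_pilot_seeds(self):
        des = self._design()

        def gen(seed):
            d2 = dataclasses.replace(des, seed=seed)
            return scenario_calibration(d2).admin_cutoff

        c1, c2 = gen(5), gen(6)
        assert abs(c1 - c2) / c1 < 0.05

    def test_no_admin_quantile_disables_cutoff(self):
        des = self._design(admin_quantile=None)
        cal = scenario_calibration(des)
        assert cal.admin_cutoff == np.inf


class TestSimulateDataset:
    def test_bitwise_reproducible(self):
        des = SimulationDesign(n=200, d=12, rel_var=0.25, seed=9, pilot_size=20_000)
        ds1, ds2 = simulate_dataset(des), simulate_dataset(des)
        np.testing.assert_array_equal(ds1.sample.times, ds2.sample.times)
        np.testing.assert_array_equal(ds1.sample.covariates, ds2.sample.covariates)

    def test_realized_censoring_near_target(self):
        des = SimulationDesign(n=2000, d=12, rel_var=0.25, cens_rate=0.25, seed=3,
                               pilot_size=50_000)
        ds = simulate_dataset(des)
        assert 0.20 <= ds.realized_cens_rate <= 0.30

    def test_influential_mask_count(self):
        des = SimulationDesign(n=100, d=30, rel_var=0.1, seed=1, pilot_size=20_000)
        ds = simulate_dataset(des)
        assert ds.influential_mask.sum() == 3
        assert np.all(ds.beta_true[~ds.influential_mask] == 0)

    def test_empirical_correlation_matches_target(self):
        des = SimulationDesign(n=5000, d=12, rel_var=0.25, seed=21, pilot_size=20_000)
        cal = scenario_calibration(des)
        ds = simulate_dataset(dataclasses.replace(des, n=5000), cal)
        emp = np.corrcoef(ds.sample.covariates.T)
        err = np.abs(emp - ds.correlation_matrix_used)
        assert np.quantile(err, 0.95) < 0.05

    def test_lognormal_explained_variance(self):
        des = SimulationDesign(n=100_000, d=9, rel_var=0.34, exp_var=0.5, seed=13,
                               pilot_size=20_000)
        cal = scenario_calibration(des)
        rng = np.random.default_rng(5)
        Z = rng.standard_normal((des.n, des.d))
        X = Z @ cal.chol.T
        xb = X @ cal.beta
        y = xb + rng.normal(0, np.sqrt(cal.sigma_eps2), des.n)
        assert abs(np.var(xb) / np.var(y) - 0.5) < 0.02

    def test_weibull_log_linear_conditional_mean(self):
        # AFT structure: E[log T | x] is linear in x'beta with slope 1
        des = SimulationDesign(n=200_000, d=9, rel_var=0.34, family="weibull",
                               snr=0.5, seed=2, pilot_size=50_000,
                               admin_quantile=None, cens_rate=0.4)
        cal = scenario_calibration(des)
        rng = np.random.default_rng(8)
        Z = rng.standard_normal((des.n, des.d))
        X = Z @ cal.chol.T
        xb = X @ cal.beta
        T = np.exp(xb) * rng.weibull(cal.shape, des.n)
        resid = np.log(T) - xb
        bins = np.quantile(xb, np.linspace(0.05, 0.95, 7))
        idx = np.digitize(xb, bins)
        bin_means = [resid[idx == b].mean() for b in range(1, 7)]
        # conditional mean of log T minus x'beta is constant in x'beta
        assert np.ptp(bin_means) < 0.05
        # and the residual variance matches pi^2 / (6 phi^2)
        assert np.var(resid) == pytest.approx(np.pi**2 / 6 / cal.shape**2, rel=0.02)

    def test_spillover_when_block_too_small_warns(self):
        with pytest.warns(UserWarning, match="spilling"):
            des = SimulationDesign(n=50, d=9, rel_var=0.5, signal_block=1, seed=0,
                                   pilot_size=10_000)
            scenario_calibration(des)
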