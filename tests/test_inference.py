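from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

import tvcox as tv


@pytest.fixture(scope="module")
def fitted(small_data, basis_k4):
    return tv.fit_coxtv(small_data, basis_k4)


class TestPH:
    def test_constant_row_gives_zero_statistic(self, fitted, basis_k4):
        cm = tv.CoefficientMatrix(
            np.array([[0.7, 0.7, 0.7, 0.7], [0.1, 0.2, 0.3, 0.4]]),
            basis_k4,
            fitted.theta_hat.covariate_names,
        )
        m = replace(fitted, theta_hat=cm)
        r = tv.test_ph(m, "z1")
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_k2_scalar_contrast_closed_form(self, small_data):
        basis = tv.make_basis(
            np.unique(small_data.time[small_data.event == 1]), K=2, degree=1
        )
        m = tv.fit_coxtv(small_data, basis)
        r = tv.test_ph(m, "z1")
        V = m.covariance_block(0)
        diff = m.theta_hat.theta[0, 1] - m.theta_hat.theta[0, 0]
        var = V[0, 0] + V[1, 1] - 2 * V[0, 1]
        assert r.df == 1
        assert r.statistic == pytest.approx(diff**2 / var, rel=1e-10)

    def test_invariant_to_contrast_basis(self, fitted):
        # any (K-1) x K full-rank matrix annihilating constants gives the
        # same Wald statistic
        K = fitted.K
        j = 1
        theta_j = fitted.theta_hat.theta[j]
        V = fitted.covariance_block(j)
        C1 = np.diff(np.eye(K), axis=0)
        C2 = np.eye(K)[1:] - np.eye(K)[0]  # deviations from the first
        stats_ = []
        for C in (C1, C2):
            est = C @ theta_j
            stats_.append(est @ np.linalg.solve(C @ V @ C.T, est))
        assert stats_[0] == pytest.approx(stats_[1], rel=1e-9)
        r = tv.test_ph(fitted, j)
        assert r.statistic == pytest.approx(stats_[0], rel=1e-12)

    def test_k1_rejected(self, small_data):
        basis = tv.make_basis(
            np.unique(small_data.time[small_data.event == 1]), K=1, degree=0
        )
        m = tv.fit_coxtv(small_data, basis)
        with pytest.raises(ValueError, match="K >= 2"):
            tv.test_ph(m, "z1")


class TestZero:
    def test_zero_theta_gives_zero_statistic(self, fitted, basis_k4):
        cm = tv.CoefficientMatrix(
            np.vstack([np.zeros(4), fitted.theta_hat.theta[1]]),
            basis_k4,
            fitted.theta_hat.covariate_names,
        )
        m = replace(fitted, theta_hat=cm)
        r = tv.test_zero(m, "z1")
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_k1_matches_standard_cox_wald(self):
        lifelines = pytest.importorskip("lifelines")
        spec = tv.SimulationSpec(
            n=150, p=1, covariate_law=("normal",), beta_funcs=(("constant", 0.6),),
            seed=41,
        )
        data, _ = tv.simulate_dataset(spec)
        basis = tv.make_basis(np.unique(data.time[data.event == 1]), K=1, degree=0)
        m = tv.fit_coxtv(data, basis, tv.FitConfig(tol=1e-12))
        r = tv.test_zero(m, 0)
        cph = lifelines.CoxPHFitter().fit(
            data.to_frame(), "time", "event", fit_options={"precision": 1e-10}
        )
        z = (cph.params_.values[0] / cph.standard_errors_.values[0]) ** 2
        assert r.df == 1
        assert r.statistic == pytest.approx(z, rel=1e-4)


class TestPointwiseAndBands:
    def test_zero_theta_all_statistics_zero(self, fitted, basis_k4):
        cm = tv.CoefficientMatrix(np.zeros((2, 4)), basis_k4,
                                  fitted.theta_hat.covariate_names)
        m = replace(fitted, theta_hat=cm)
        r = tv.test_pointwise(m, "z2", times=np.linspace(0.2, 2.5, 10))
        np.testing.assert_allclose(r.statistic, 0.0, atol=1e-12)

    def test_pointwise_consistent_with_confint(self, fitted):
        times = np.linspace(*fitted.basis.boundary, 15)
        r = tv.test_pointwise(fitted, "z2", times)
        ci = tv.confint_tvef(fitted, "z2", times, level=0.95)
        zq = stats.norm.ppf(0.975)
        se = (ci["upper"] - ci["estimate"]) / zq
        np.testing.assert_allclose(
            np.sqrt(r.statistic), np.abs(ci["estimate"]) / se, rtol=1e-10
        )

    def test_pointwise_variance_delta_method(self, fitted):
        times = np.array([0.5, 1.0, 2.0])
        j = fitted.covariate_index("z1")
        B = fitted.basis.evaluate(times)
        V = fitted.covariance_block(j)
        expected_var = np.array([b @ V @ b for b in B])
        beta = B @ fitted.theta_hat.theta[j]
        r = tv.test_pointwise(fitted, "z1", times)
        np.testing.assert_allclose(r.statistic, beta**2 / expected_var, rtol=1e-12)

    def test_bonferroni_inflates_pvalues(self, fitted):
        times = np.linspace(*fitted.basis.boundary, 10)
        r0 = tv.test_pointwise(fitted, "z2", times)
        r1 = tv.test_pointwise(fitted, "z2", times, bonferroni=True)
        assert np.all(r1.p_value >= r0.p_value - 1e-15)

    def test_confint_nesting(self, fitted):
        times = np.linspace(*fitted.basis.boundary, 20)
        ci95 = tv.confint_tvef(fitted, "z2", times, level=0.95)
        ci99 = tv.confint_tvef(fitted, "z2", times, level=0.99)
        assert np.all(ci99["lower"] <= ci95["lower"] + 1e-12)
        assert np.all(ci99["upper"] >= ci95["upper"] - 1e-12)

    def test_degenerate_variance_zero_width(self, fitted, basis_k4):
        m = replace(
            fitted,
            info_inverse=np.zeros_like(fitted.info_inverse),
        )
        ci = tv.confint_tvef(m, "z1", times=[1.0], level=0.95)
        assert ci["lower"][0] == ci["estimate"][0] == ci["upper"][0]

    def test_invalid_level_rejected(self, fitted):
        with pytest.raises(ValueError, match="level"):
            tv.confint_tvef(fitted, "z1", [1.0], level=1.5)


class TestMonteCarlo:
    def test_zero_test_power_under_strong_effect(self):
        # beta = 1 constant at n=500: the zero-effect test should almost
        # always reject
        rej = 0
        reps = 200
        for s in range(reps):
            spec = tv.SimulationSpec(
                n=500, p=1, covariate_law=("normal",),
                beta_funcs=(("constant", 1.0),),
                censoring=("uniform", 6.0), t_horizon=3.0, seed=50_000 + s,
            )
            data, _ = tv.simulate_dataset(spec)
            basis = tv.make_basis(
                np.unique(data.time[data.event == 1]), K=5, degree=3
            )
            m = tv.fit_coxtv(data, basis)
            rej += tv.test_zero(m, 0).p_value < 0.05
        assert rej / reps >= 0.95

    def test_pointwise_band_coverage_at_grid_median(self):
        # 95% pointwise interval for beta(t) at the median follow-up time
        # covers the truth at close to nominal rate on a well-specified fit
        reps = 300
        cover = 0
        truth_fn = tv.sine(1.0, np.pi / 3.0)
        for s in range(reps):
            spec = tv.SimulationSpec(
                n=1000, p=1, covariate_law=("normal",),
                beta_funcs=(("sine", 1.0, np.pi / 3.0),),
                censoring=("uniform", 6.0), t_horizon=3.0, seed=60_000 + s,
            )
            data, _ = tv.simulate_dataset(spec)
            basis = tv.make_basis(
                np.unique(data.time[data.event == 1]), K=5, degree=3
            )
            m = tv.fit_coxtv(data, basis)
            t_med = float(np.median(np.unique(data.time[data.event == 1])))
            ci = tv.confint_tvef(m, 0, [t_med], level=0.95)
            truth = float(truth_fn(np.array([t_med]))[0])
            cover += bool(ci["lower"][0] <= truth <= ci["upper"][0])
        assert 0.91 <= cover / reps <= 0.98, f"coverage {cover / reps:.3f}"


class TestGetTvef:
    def test_zero_theta(self, fitted, basis_k4):
        cm = tv.CoefficientMatrix(np.zeros((2, 4)), basis_k4,
                                  fitted.theta_hat.covariate_names)
        m = replace(fitted, theta_hat=cm)
        out = tv.get_tvef(m, np.linspace(0.5, 2.0, 5))
        assert out.shape == (5, 2)
        np.testing.assert_array_equal(out.to_numpy(), 0.0)

    def test_hand_multiplication(self, small_data):
        basis = tv.make_basis(
            np.unique(small_data.time[small_data.event == 1]), K=3, degree=2
        )
        theta = np.array([[1.0, 2.0, 3.0], [-1.0, 0.5, 0.0]])
        m = tv.fit_coxtv(small_data, basis)
        m = replace(
            m, theta_hat=tv.CoefficientMatrix(theta, basis, ["z1", "z2"])
        )
        t = 1.3
        B = basis.evaluate([t])[0]
        out = tv.get_tvef(m, [t])
        np.testing.assert_allclose(out.to_numpy()[0], [B @ theta[0], B @ theta[1]])

    def test_single_time_matches_linear_predictor_units(self, fitted):
        t = 1.1
        out = tv.get_tvef(fitted, [t]).to_numpy()[0]
        for j in range(fitted.p):
            e = np.zeros(fitted.p)
            e[j] = 1.0
            assert out[j] == pytest.approx(
                tv.linear_predictor(fitted.theta_hat, e, t), rel=1e-12
            )

    def test_unknown_covariate_rejected(self, fitted):
        with pytest.raises(KeyError):
            tv.test_zero(fitted, "nope")
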