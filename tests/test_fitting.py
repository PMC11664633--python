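import numpy as np
import pytest

import tvcox as tv
from _oracles import expanded_newton_fit


def _basis(data, K, degree=3):
    return tv.make_basis(np.unique(data.time[data.event == 1]), K=K, degree=degree)


class TestCoxtv:
    def test_constant_basis_matches_standard_cox(self):
        lifelines = pytest.importorskip("lifelines")
        spec = tv.SimulationSpec(
            n=50, p=2, beta_funcs=(("constant", 0.8), ("constant", -0.4)), seed=13
        )
        data, _ = tv.simulate_dataset(spec)
        basis = _basis(data, K=1, degree=0)
        m = tv.fit_coxtv(data, basis, tv.FitConfig(tol=1e-12))
        cph = lifelines.CoxPHFitter().fit(
            data.to_frame(), "time", "event", fit_options={"precision": 1e-10}
        )
        np.testing.assert_allclose(
            m.theta_hat.theta.ravel(), cph.params_.values, atol=1e-6
        )

    def test_zero_covariate_stays_zero(self, small_data):
        z = small_data.z.copy()
        z[:, 1] = 0.0
        data = tv.SurvivalDataset(
            z=z, time=small_data.time, event=small_data.event,
            covariate_names=["z1", "z2"],
        )
        basis = _basis(data, K=4)
        m = tv.fit_coxtv(data, basis)
        np.testing.assert_allclose(m.theta_hat.theta[1], 0.0, atol=1e-12)
        risk = tv.build_risk_sets(data)
        ev = tv.log_partial_likelihood(m.theta_hat, data, risk, want="value_grad")
        np.testing.assert_allclose(ev.gradient[basis.K :], 0.0, atol=1e-12)

    def test_tiny_fixture_matches_expansion_oracle(self):
        spec = tv.SimulationSpec(
            n=6, p=1, covariate_law=("normal",), beta_funcs=(("constant", 0.5),),
            seed=17,
        )
        data, _ = tv.simulate_dataset(spec)
        basis = _basis(data, K=2, degree=1)
        m = tv.fit_coxtv(data, basis, tv.FitConfig(tol=1e-13))
        theta_oracle, _ = expanded_newton_fit(data, basis)
        np.testing.assert_allclose(m.theta_hat.theta, theta_oracle, atol=1e-8)

    @pytest.mark.parametrize(
        "n,p,K,degree", [(40, 1, 3, 2), (80, 2, 4, 3), (100, 3, 5, 3)]
    )
    def test_kronecker_vs_expansion_oracle(self, n, p, K, degree):
        spec = tv.SimulationSpec(
            n=n, p=p,
            covariate_law=tuple(["normal"] * p),
            beta_funcs=tuple([("constant", 0.4)] * p),
            tie_rounding=1 if n >= 80 else None,
            seed=n + p,
        )
        data, _ = tv.simulate_dataset(spec)
        basis = _basis(data, K=K, degree=degree)
        m = tv.fit_coxtv(data, basis, tv.FitConfig(tol=1e-12))
        theta_oracle, _ = expanded_newton_fit(data, basis)
        np.testing.assert_allclose(m.theta_hat.theta, theta_oracle, atol=1e-6)

    def test_monotone_ascent_trace(self, small_data):
        m = tv.fit_coxtv(small_data, _basis(small_data, K=4))
        assert np.all(np.diff(m.trace) >= 0)
        assert m.converged

    def test_permutation_invariance(self, small_data):
        basis = _basis(small_data, K=4)
        m1 = tv.fit_coxtv(small_data, basis)
        rng = np.random.default_rng(19)
        perm = rng.permutation(small_data.n)
        m2 = tv.fit_coxtv(small_data.subset(perm), basis)
        np.testing.assert_allclose(
            m1.theta_hat.theta, m2.theta_hat.theta, atol=1e-10
        )

    def test_stratified_single_stratum_equals_unstratified(self, small_data):
        basis = _basis(small_data, K=4)
        m1 = tv.fit_coxtv(small_data, basis)
        lab = tv.SurvivalDataset(
            z=small_data.z, time=small_data.time, event=small_data.event,
            stratum=np.zeros(small_data.n, dtype=int),
            covariate_names=small_data.covariate_names,
        )
        m2 = tv.fit_coxtv(lab, basis)
        np.testing.assert_array_equal(m1.theta_hat.theta, m2.theta_hat.theta)

    def test_stratified_fit_matches_expansion_oracle(self, strat_data):
        basis = _basis(strat_data, K=3, degree=2)
        m = tv.fit_coxtv(strat_data, basis, tv.FitConfig(tol=1e-12))
        theta_oracle, _ = expanded_newton_fit(strat_data, basis)
        np.testing.assert_allclose(m.theta_hat.theta, theta_oracle, atol=1e-6)


class TestCoxtp:
    def test_lambda_zero_identical_to_coxtv(self, small_data):
        basis = _basis(small_data, K=4)
        m1 = tv.fit_coxtv(small_data, basis)
        pen = tv.make_penalty("pspline", basis, lam=0.0)
        m2 = tv.fit_coxtp(small_data, basis, pen)
        np.testing.assert_allclose(
            m1.theta_hat.theta, m2.theta_hat.theta, atol=1e-10
        )

    def test_penalized_matches_expansion_oracle(self, small_data):
        basis = _basis(small_data, K=4)
        pen = tv.make_penalty("pspline", basis, lam=2.5)
        m = tv.fit_coxtp(small_data, basis, pen, tv.FitConfig(tol=1e-12))
        theta_oracle, _ = expanded_newton_fit(small_data, basis, S=pen.S, lam=2.5)
        np.testing.assert_allclose(m.theta_hat.theta, theta_oracle, atol=1e-6)

    def test_huge_pspline_order1_gives_constant_effect(self):
        spec = tv.SimulationSpec(n=300, p=2, seed=23)
        data, _ = tv.simulate_dataset(spec)
        basis = _basis(data, K=6)
        pen = tv.make_penalty("pspline", basis, lam=1e8, diff_order=1)
        m = tv.fit_coxtp(data, basis, pen)
        grid = np.linspace(*basis.boundary, 100)
        beta = m.theta_hat.beta_at(grid)
        assert np.abs(beta - beta.mean(axis=0)).max() < 1e-4
        # the limiting constant is the standard Cox coefficient
        lifelines = pytest.importorskip("lifelines")
        cph = lifelines.CoxPHFitter().fit(data.to_frame(), "time", "event")
        np.testing.assert_allclose(beta.mean(axis=0), cph.params_.values, atol=1e-3)

    def test_huge_smoothing_spline_gives_linear_effect(self):
        spec = tv.SimulationSpec(n=300, p=2, seed=29)
        data, _ = tv.simulate_dataset(spec)
        basis = _basis(data, K=6)
        pen = tv.make_penalty("smoothing_spline", basis, lam=1e8)
        m = tv.fit_coxtp(data, basis, pen)
        grid = np.linspace(*basis.boundary, 100)
        beta = m.theta_hat.beta_at(grid)
        X = np.column_stack([np.ones_like(grid), grid])
        resid = beta - X @ np.linalg.lstsq(X, beta, rcond=None)[0]
        assert np.abs(resid).max() < 1e-4

    def test_monotone_ascent_penalized(self, small_data):
        basis = _basis(small_data, K=4)
        for lam in (0.1, 10.0, 1e4):
            m = tv.fit_coxtp(small_data, basis, tv.make_penalty("pspline", basis, lam=lam))
            assert np.all(np.diff(m.trace) >= 0)


class TestPath:
    def test_single_lambda_same_as_coxtp(self, small_data):
        basis = _basis(small_data, K=4)
        (m,) = tv.fit_path(small_data, basis, "pspline", [3.0])
        m2 = tv.fit_coxtp(small_data, basis, tv.make_penalty("pspline", basis, lam=3.0))
        np.testing.assert_allclose(m.theta_hat.theta, m2.theta_hat.theta, atol=1e-9)

    def test_warm_started_path_ends_at_unpenalized(self, small_data):
        basis = _basis(small_data, K=4)
        path = tv.fit_path(small_data, basis, "pspline", [1e8, 1.0, 0.0])
        m_tv = tv.fit_coxtv(small_data, basis)
        assert path[0].penalty.lam == 1e8
        np.testing.assert_allclose(
            path[-1].theta_hat.theta, m_tv.theta_hat.theta, atol=1e-6
        )

    def test_each_fit_is_local_optimum(self, small_data):
        basis = _basis(small_data, K=4)
        risk = tv.build_risk_sets(small_data)
        path = tv.fit_path(small_data, basis, "pspline", [0.1, 10.0])
        rng = np.random.default_rng(31)
        for m in path:
            cm = m.theta_hat
            ev = tv.log_partial_likelihood(cm, small_data, risk, want="value")
            best, _, _ = tv.penalized_objective(cm, ev, m.penalty)
            for _ in range(20):
                pert = tv.CoefficientMatrix(
                    cm.theta + rng.normal(scale=0.05, size=cm.theta.shape),
                    basis,
                    cm.covariate_names,
                )
                evp = tv.log_partial_likelihood(pert, small_data, risk, want="value")
                val, _, _ = tv.penalized_objective(pert, evp, m.penalty)
                assert val <= best + 1e-10


def test_unconverged_flag_is_honest(small_data):
    basis = _basis(small_data, K=4)
    m = tv.fit_coxtv(small_data, basis, tv.FitConfig(max_iter=1))
    assert not m.converged
    assert m.n_iter == 1
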