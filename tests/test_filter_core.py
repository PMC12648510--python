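"""Variational update engine: Newton equivalence, energies, fixed points,
limits, prediction correlation, full trajectory properties."""

import numpy as np
import pytest
from conftest import random_belief

from expvol.filter_core import (
    FilterConfig,
    GaussianBelief,
    LevelOnePrediction,
    ModelParams,
    default_params,
    grad_V1,
    hess_V1,
    predict_level1,
    prediction_correlation,
    run_filter,
    total_predictive_loglik,
    update_level1,
    update_level2,
    variational_energy_V1,
    variational_energy_V2,
)
from expvol.hyper_learning import fd_gradient, fd_hessian
from expvol.synthetic_data import make_benchmark


def scalar_params(**kw):
    base = dict(
        w1=[1.0], b1=[0.0], w2=[1.0], b2=[0.0], lam=[0.02],
        mu1_0=[0.0], C1_0=np.eye(1), mu2_0=[0.0], C2_0=np.eye(1),
    )
    base.update(kw)
    return ModelParams(**base)


class TestPredictLevel1:
    def test_zero_volatility_state_gives_identity_sigma(self):
        params = default_params(2)
        b1 = GaussianBelief.from_moments(np.zeros(2), np.eye(2))
        b2 = GaussianBelief.from_moments(np.zeros(3), np.eye(3))
        pred = predict_level1(b1, b2, params, FilterConfig())
        np.testing.assert_allclose(pred.Sigma1_hat, np.eye(2), atol=1e-14)
        np.testing.assert_allclose(pred.Pi1_hat, np.eye(2) / 2.0, atol=1e-14)

    def test_epsilon_zero_limit_recovers_prior_precision(self, rng):
        params = default_params(2)
        b1 = random_belief(rng, 2)
        b2 = random_belief(rng, 3)
        pred = predict_level1(b1, b2, params, FilterConfig(epsilon=1e-12))
        np.testing.assert_allclose(pred.Pi1_hat, b1.P, atol=1e-8)

    def test_cholesky_inverse_matches_dense_inverse(self, rng):
        params = default_params(2)
        for _ in range(20):
            b1 = random_belief(rng, 2)
            b2 = random_belief(rng, 3)
            pred = predict_level1(b1, b2, params, FilterConfig())
            dense = np.linalg.inv(pred.S_pred)
            np.testing.assert_allclose(pred.Pi1_hat, dense, atol=1e-10)


class TestUpdateLevel1:
    def test_hand_computed_scalar_chain(self):
        """d1=1, w1=1, mu=0 (r̂=1), o=2, Π̂1=0.5: P1=2.5, C1=0.4, PE0=−1, μ1=−0.4."""
        params = scalar_params()
        b1 = GaussianBelief.from_moments(np.zeros(1), np.eye(1))
        pred = LevelOnePrediction(
            r_hat=np.array([1.0]), L1_hat=np.eye(1), Sigma1_hat=np.eye(1),
            S_pred=np.array([[2.0]]), Pi1_hat=np.array([[0.5]]),
        )
        belief, PE0 = update_level1(np.array([2.0]), b1, pred, params, FilterConfig())
        assert belief.P[0, 0] == pytest.approx(2.5)
        assert belief.C[0, 0] == pytest.approx(0.4)
        assert PE0[0] == pytest.approx(-1.0)
        assert belief.mu[0] == pytest.approx(-0.4)

    def test_zero_prediction_error_fixed_point(self, rng):
        params = default_params(2)
        b1 = random_belief(rng, 2)
        b2 = random_belief(rng, 3)
        pred = predict_level1(b1, b2, params, FilterConfig())
        o = 1.0 / pred.r_hat
        belief, PE0 = update_level1(o, b1, pred, params, FilterConfig())
        np.testing.assert_allclose(PE0, 0.0, atol=1e-14)
        np.testing.assert_allclose(belief.mu, b1.mu, atol=1e-12)
        # covariance still shrinks: P1 - Pi1_hat is PSD and nonzero
        assert np.linalg.eigvalsh(belief.P - pred.Pi1_hat).min() >= -1e-10
        assert np.trace(belief.P - pred.Pi1_hat) > 0

    @pytest.mark.parametrize("d1", [1, 2, 3])
    def test_equals_newton_step_on_fd_energy(self, d1, rng):
        params = default_params(d1)
        d2 = d1 * (d1 + 1) // 2
        for _ in range(7):
            b1 = random_belief(rng, d1)
            b2 = random_belief(rng, d2, 0.3)
            pred = predict_level1(b1, b2, params, FilterConfig())
            o = rng.exponential(1.0 / pred.r_hat)
            belief, _ = update_level1(o, b1, pred, params, FilterConfig())

            def V(x):
                return variational_energy_V1(x, o, b1, pred, params)

            g = fd_gradient(V, b1.mu)
            H = fd_hessian(V, b1.mu)
            newton = b1.mu - np.linalg.solve(H, g)
            rel = np.max(np.abs(newton - belief.mu)) / max(1.0, np.max(np.abs(belief.mu)))
            assert rel < 1e-5

    def test_precision_dominates_prediction_precision(self, rng):
        params = default_params(2)
        for _ in range(10):
            b1 = random_belief(rng, 2)
            b2 = random_belief(rng, 3)
            pred = predict_level1(b1, b2, params, FilterConfig())
            o = rng.exponential(1.0 / pred.r_hat)
            belief, _ = update_level1(o, b1, pred, params, FilterConfig())
            assert np.linalg.eigvalsh(belief.P - pred.Pi1_hat).min() >= -1e-10


class TestVariationalEnergyV1:
    @pytest.mark.parametrize("d1", [1, 2, 3])
    def test_analytic_gradient_and_hessian_match_fd(self, d1, rng):
        params = default_params(d1)
        d2 = d1 * (d1 + 1) // 2
        for _ in range(7):
            b1 = random_belief(rng, d1)
            b2 = random_belief(rng, d2, 0.3)
            pred = predict_level1(b1, b2, params, FilterConfig())
            o = rng.exponential(1.0 / pred.r_hat)
            x = b1.mu + rng.uniform(-0.5, 0.5, d1)

            def V(t):
                return variational_energy_V1(t, o, b1, pred, params)

            g = grad_V1(x, o, b1, pred, params)
            H = hess_V1(x, o, b1, pred, params)
            g_fd = fd_gradient(V, x)
            H_fd = fd_hessian(V, x)
            assert np.max(np.abs(g - g_fd)) / max(1.0, np.max(np.abs(g_fd))) < 1e-6
            assert np.max(np.abs(H - H_fd)) / np.max(np.abs(H_fd)) < 1e-5

    def test_gradient_zero_at_consistent_stationary_point(self, rng):
        params = default_params(2)
        b1 = random_belief(rng, 2)
        b2 = random_belief(rng, 3)
        pred = predict_level1(b1, b2, params, FilterConfig())
        o = 1.0 / pred.r_hat  # o(i)·exp(W1 x1 + b1)(i) = 1 at x1 = mu1_prev
        g = grad_V1(b1.mu, o, b1, pred, params)
        np.testing.assert_allclose(g, 0.0, atol=1e-12)


class TestUpdateLevel2:
    def test_zero_delta_freezes_mean(self, rng):
        params = default_params(2)
        b1 = random_belief(rng, 2)
        b2 = random_belief(rng, 3)
        cfg = FilterConfig()
        pred = predict_level1(b1, b2, params, cfg)
        # engineered posterior making Δ1 = 0: same mean (PE1=0), C1 = Π̂1⁻¹
        b1_new = GaussianBelief.from_moments(b1.mu.copy(), pred.S_pred)
        b2_new, inter, _ = update_level2(b2, b1, b1_new, pred, params, cfg)
        np.testing.assert_allclose(inter.Delta1, 0.0, atol=1e-10)
        np.testing.assert_allclose(b2_new.mu, b2.mu, atol=1e-10)

    def test_epsilon_zero_freezes_level2(self, rng):
        params = default_params(2)
        b1 = random_belief(rng, 2)
        b2 = random_belief(rng, 3)
        cfg = FilterConfig(epsilon=1e-12)
        pred = predict_level1(b1, b2, params, cfg)
        o = rng.exponential(1.0 / pred.r_hat)
        b1_new, _ = update_level1(o, b1, pred, params, cfg)
        b2_new, _, _ = update_level2(b2, b1, b1_new, pred, params, cfg)
        np.testing.assert_allclose(b2_new.mu, b2.mu, atol=1e-8)
        np.testing.assert_allclose(b2_new.P, b2.P, atol=1e-8)

    def test_drive_matches_v2_gradient(self, rng):
        """The mean-update drive is the gradient of the reference V2 at μ2,k−1."""
        params = default_params(2)
        for eps in [1.0, 0.1]:
            cfg = FilterConfig(epsilon=eps)
            b1 = random_belief(rng, 2)
            b2 = random_belief(rng, 3, 0.5)
            pred = predict_level1(b1, b2, params, cfg)
            o = rng.exponential(1.0 / pred.r_hat)
            b1_new, _ = update_level1(o, b1, pred, params, cfg)
            _, inter, _ = update_level2(b2, b1, b1_new, pred, params, cfg)
            drive = eps * params.w2 * (
                inter.Lg @ (inter.Delta1.T @ inter.Omega1_hat.T).reshape(-1, order="F")
            )
            g = fd_gradient(
                lambda x: variational_energy_V2(x, b2, b1, b1_new, params, cfg), b2.mu
            )
            assert np.linalg.norm(drive - g) / np.linalg.norm(g) < 1e-4


class TestVariationalEnergyV2:
    def test_stationary_when_delta_zero(self, rng):
        params = default_params(2)
        cfg = FilterConfig()
        b1 = random_belief(rng, 2)
        b2 = random_belief(rng, 3)
        pred = predict_level1(b1, b2, params, cfg)
        b1_new = GaussianBelief.from_moments(b1.mu.copy(), pred.S_pred)
        g = fd_gradient(
            lambda x: variational_energy_V2(x, b2, b1, b1_new, params, cfg), b2.mu
        )
        np.testing.assert_allclose(g, 0.0, atol=1e-8)

    def test_terms_against_dense_oracle(self, rng):
        from expvol.volatility_param import volatility_factor

        params = default_params(2)
        cfg = FilterConfig()
        b1 = random_belief(rng, 2)
        b2 = random_belief(rng, 3)
        b1_new = random_belief(rng, 2)
        x2 = rng.standard_normal(3)
        got = variational_energy_V2(x2, b2, b1, b1_new, params, cfg)
        A = cfg.epsilon * volatility_factor(x2, params.vol_coupling).Sigma1 + b1.C
        PE1 = b1_new.mu - b1.mu
        M = b1_new.C + np.outer(PE1, PE1)
        Pi2 = np.linalg.inv(cfg.epsilon * params.Sigma2 + b2.C)
        d = x2 - b2.mu
        want = (
            -0.5 * np.linalg.slogdet(A)[1]
            - 0.5 * np.trace(np.linalg.solve(A, M))
            - 0.5 * d @ Pi2 @ d
        )
        assert got == pytest.approx(want, rel=1e-10)

    def test_invariant_under_dimension_relabeling(self, rng):
        """For d1=2 with exchangeable parameters and isotropic covariances,
        swapping the two signal dimensions permutes x2 as (3,2,1) and
        leaves V2 unchanged (the swapped volatility matrix is isospectral)."""
        params = default_params(2)
        cfg = FilterConfig()
        b1 = GaussianBelief.from_moments(np.zeros(2), 0.7 * np.eye(2))
        b2 = GaussianBelief.from_moments(np.zeros(3), 1.3 * np.eye(3))
        b1_new = GaussianBelief.from_moments(np.zeros(2), 0.4 * np.eye(2))
        for _ in range(10):
            x2 = rng.standard_normal(3)
            v = variational_energy_V2(x2, b2, b1, b1_new, params, cfg)
            v_sw = variational_energy_V2(x2[::-1].copy(), b2, b1, b1_new, params, cfg)
            assert v == pytest.approx(v_sw, rel=1e-12)


class TestPredictionCorrelation:
    def test_diagonal_prediction_gives_zero(self):
        pred = LevelOnePrediction(
            r_hat=np.ones(2), L1_hat=np.eye(2), Sigma1_hat=np.eye(2),
            S_pred=2.0 * np.eye(2), Pi1_hat=0.5 * np.eye(2),
        )
        assert prediction_correlation(pred) == pytest.approx(0.0)

    def test_hand_computed_cholesky_case(self):
        # L̂1 = [[1,0],[1,1]], C_prev -> 0: S = [[1,1],[1,2]], rho = 1/sqrt(2)
        L = np.array([[1.0, 0.0], [1.0, 1.0]])
        S = L @ L.T
        pred = LevelOnePrediction(
            r_hat=np.ones(2), L1_hat=L, Sigma1_hat=S, S_pred=S, Pi1_hat=np.linalg.inv(S)
        )
        assert prediction_correlation(pred) == pytest.approx(1.0 / np.sqrt(2.0))

    def test_bounded_by_one(self, rng):
        from conftest import random_spd

        for _ in range(20):
            S = random_spd(rng, 2)
            pred = LevelOnePrediction(
                r_hat=np.ones(2), L1_hat=np.eye(2), Sigma1_hat=S,
                S_pred=S, Pi1_hat=np.linalg.inv(S),
            )
            assert abs(prediction_correlation(pred)) < 1.0

    def test_matrix_output_for_higher_dimensions(self, rng):
        params = default_params(3)
        b1 = random_belief(rng, 3)
        b2 = random_belief(rng, 6)
        pred = predict_level1(b1, b2, params, FilterConfig())
        R = prediction_correlation(pred)
        assert R.shape == (3, 3)
        np.testing.assert_allclose(np.diag(R), 1.0)


class TestRunFilter:
    def test_constant_observations_at_prior_mean_rate_freeze_mu1(self):
        params = default_params(2)
        r0 = np.exp(params.w1 * params.mu1_0 + params.b1)
        obs = np.tile(1.0 / r0, (20, 1))
        traj = run_filter(obs, params)
        for rec in traj:
            np.testing.assert_allclose(rec.belief1.mu, params.mu1_0, atol=1e-10)

    def test_benchmark_run_all_finite_and_spd(self):
        ds = make_benchmark(K=400, seed=12)
        traj = run_filter(ds.observations, default_params(2))
        assert len(traj) == 400
        for rec in traj:
            assert np.all(np.isfinite(rec.belief1.mu))
            assert np.all(np.isfinite(rec.belief2.mu))
            np.linalg.cholesky(rec.belief1.C)
            np.linalg.cholesky(rec.belief2.C)
            assert np.isfinite(rec.pred_loglik)
            assert -1.0 < rec.rho1 < 1.0

    def test_no_jitter_escalation_on_benchmark(self):
        ds = make_benchmark(K=400, seed=12)
        traj = run_filter(ds.observations, default_params(2))
        assert max(rec.jitter for rec in traj) <= 1e-9  # at most one guard step

    def test_rejects_negative_observation_with_location(self):
        obs = np.ones((5, 2))
        obs[2, 1] = -0.5
        with pytest.raises(ValueError, match="row 3, column 2"):
            run_filter(obs, default_params(2))

    def test_lightweight_pass_matches_loglik(self):
        ds = make_benchmark(K=50, seed=4)
        params = default_params(2)
        full = run_filter(ds.observations, params, records=True)
        lite = run_filter(ds.observations, params, records=False)
        assert total_predictive_loglik(full) == total_predictive_loglik(lite)
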