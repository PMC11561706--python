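import numpy as np
import pytest
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel

from clockshift import (GPRClock, KernelParams, SimulationConfig, fit_gpr,
                        log_marginal_likelihood, predict_gpr, rbf_kernel,
                        simulate_aging_methylation, simulate_reprogramming_course)

UNIT_PARAMS = KernelParams(s2=1.0, length_scale=1.0, noise=1.0)


def brute_force_posterior(X, y_centered, X_new, params):
    """Dense-inverse posterior mean and latent variance (small-n oracle)."""
    K = rbf_kernel(X, X, params) + params.noise * np.eye(len(X))
    K_inv = np.linalg.inv(K)
    k_star = rbf_kernel(X, X_new, params)
    mu = k_star.T @ K_inv @ y_centered
    var = params.s2 - np.einsum("ij,ji->i", k_star.T, K_inv @ k_star)
    return mu, var


class TestRBFKernel:
    def test_zero_distance_gives_s2(self):
        params = KernelParams(s2=3.5, length_scale=0.7, noise=0.1)
        x = np.array([[0.2, 0.4]])
        assert rbf_kernel(x, x, params)[0, 0] == pytest.approx(3.5)

    def test_unit_distance_value(self):
        k = rbf_kernel(np.array([[0.0]]), np.array([[1.0]]), UNIT_PARAMS)
        assert k[0, 0] == pytest.approx(np.exp(-0.5), abs=1e-10)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(8, 3))
        params = KernelParams(s2=2.0, length_scale=0.3, noise=0.1)
        K = rbf_kernel(X, X, params)
        assert np.allclose(K, K.T)
        assert (K > 0).all() and (K <= params.s2 + 1e-12).all()

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            rbf_kernel(np.zeros((2, 2)), np.zeros((2, 3)), UNIT_PARAMS)

    def test_positive_params_required(self):
        with pytest.raises(ValueError):
            KernelParams(s2=0.0, length_scale=1.0, noise=1.0)


class TestLogMarginalLikelihood:
    def test_single_point_univariate_normal(self):
        y1 = 0.8
        value = log_marginal_likelihood(np.array([[0.3]]), np.array([y1]), UNIT_PARAMS)
        variance = UNIT_PARAMS.s2 + UNIT_PARAMS.noise
        expected = -0.5 * (np.log(2 * np.pi * variance) + y1**2 / variance)
        assert value == pytest.approx(expected, abs=1e-12)

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n, d = rng.integers(2, 8), rng.integers(1, 4)
            X = rng.uniform(size=(n, d))
            y = rng.normal(size=n)
            params = KernelParams(s2=rng.uniform(0.5, 3), length_scale=rng.uniform(0.2, 2),
                                  noise=rng.uniform(0.05, 1))
            K = rbf_kernel(X, X, params) + params.noise * np.eye(n)
            sign, logdet = np.linalg.slogdet(K)
            expected = -0.5 * (y @ np.linalg.inv(K) @ y + logdet + n * np.log(2 * np.pi))
            got = log_marginal_likelihood(X, y, params)
            assert got == pytest.approx(expected, abs=1e-8)

    def test_zero_targets_leave_determinant_term(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(5, 2))
        params = KernelParams(s2=2.0, length_scale=0.5, noise=0.3)
        K = rbf_kernel(X, X, params) + params.noise * np.eye(5)
        _, logdet = np.linalg.slogdet(K)
        expected = -0.5 * (logdet + 5 * np.log(2 * np.pi))
        assert log_marginal_likelihood(X, np.zeros(5), params) == pytest.approx(expected)


class TestFit:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(size=(30, 2))
        y = 40 + 20 * X[:, 0] + rng.normal(0, 1, size=30)
        a = GPRClock.fit(X, y, restarts=3, seed=5)
        b = GPRClock.fit(X, y, restarts=3, seed=5)
        assert a.params == b.params

    def test_recovers_known_hyperparameters(self):
        """Factor-2 recovery of (s², l, σ²) from a known GP draw."""
        truth = KernelParams(s2=4.0, length_scale=0.5, noise=0.1)
        rng = np.random.default_rng(10)
        X = rng.uniform(0, 5, size=(200, 2))
        K = rbf_kernel(X, X, truth) + truth.noise * np.eye(200)
        y = rng.multivariate_normal(np.zeros(200), K) + 50.0
        fit = GPRClock.fit(X, y, restarts=5, seed=10)
        for got, want in ((fit.params.s2, truth.s2),
                          (fit.params.length_scale, truth.length_scale),
                          (fit.params.noise, truth.noise)):
            assert want / 2 <= got <= want * 2

    def test_pure_noise_targets_absorbed_by_noise_kernel(self):
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X = rng.uniform(size=(40, 1))
            y = rng.normal(50, 5, size=40)  # no structure in X at all
            fit = GPRClock.fit(X, y, restarts=3, seed=seed)
            assert fit.params.noise >= fit.params.s2

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 training samples"):
            GPRClock.fit(np.zeros((2, 1)), np.zeros(2))


class TestPredict:
    def test_single_training_point_hand_case(self):
        clock = GPRClock(X=np.array([[0.0]]), y_centered=np.array([1.0]), y_offset=0.0,
                         params=UNIT_PARAMS)
        mu, var = clock.predict(np.array([[0.0]]))
        assert mu[0] == pytest.approx(0.5, abs=1e-12)
        assert var[0] == pytest.approx(0.5, abs=1e-12)

    def test_matches_dense_oracle_small_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n, d = rng.integers(1, 6), rng.integers(1, 4)
            X = rng.uniform(size=(n, d))
            y = rng.normal(size=n)
            params = KernelParams(s2=rng.uniform(0.5, 4), length_scale=rng.uniform(0.2, 2),
                                  noise=rng.uniform(0.05, 1))
            clock = GPRClock(X=X, y_centered=y, y_offset=0.0, params=params)
            X_new = rng.uniform(-0.5, 1.5, size=(4, d))
            mu, var = clock.predict(X_new)
            mu_oracle, var_oracle = brute_force_posterior(X, y, X_new, params)
            assert np.allclose(mu, mu_oracle, atol=1e-8)
            assert np.allclose(var, np.maximum(var_oracle, 0.0), atol=1e-8)

    def test_matches_sklearn_gpr_at_fixed_hyperparameters(self):
        """Independent cross-check: sklearn GP with the same kernel and noise
        (as alpha) reproduces posterior mean and latent SD."""
        rng = np.random.default_rng(6)
        X = rng.uniform(size=(25, 3))
        y = 30 + 15 * X[:, 0] - 8 * X[:, 2] + rng.normal(0, 0.5, size=25)
        params = KernelParams(s2=9.0, length_scale=0.8, noise=0.25)
        clock = GPRClock(X=X, y_centered=y - y.mean(), y_offset=float(y.mean()),
                         params=params)
        kernel = ConstantKernel(params.s2, "fixed") * RBF(params.length_scale, "fixed")
        sk = GaussianProcessRegressor(kernel=kernel, alpha=params.noise, optimizer=None)
        sk.fit(X, y - y.mean())  # same zero-mean convention: center, add back
        X_new = rng.uniform(-0.2, 1.2, size=(10, 3))
        mu, var = clock.predict(X_new)
        mu_sk, sd_sk = sk.predict(X_new, return_std=True)
        assert np.allclose(mu, mu_sk + y.mean(), atol=1e-7)
        assert np.allclose(np.sqrt(var), sd_sk, atol=1e-7)

    def test_far_query_hits_variance_ceiling_and_mean_offset(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(size=(20, 2))
        y = rng.normal(55, 8, size=20)
        clock = GPRClock(X=X, y_centered=y - y.mean(), y_offset=float(y.mean()),
                         params=KernelParams(s2=16.0, length_scale=0.4, noise=1.0))
        mu, var = clock.predict(np.array([[50.0, 50.0]]))
        assert var[0] == pytest.approx(16.0, abs=1e-10)
        assert mu[0] == pytest.approx(clock.y_offset, abs=1e-10)

    def test_variance_monotone_along_outbound_ray(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(size=(30, 2))
        y = rng.normal(40, 5, size=30)
        params = KernelParams(s2=4.0, length_scale=0.3, noise=0.5)
        clock = GPRClock(X=X, y_centered=y - y.mean(), y_offset=float(y.mean()),
                         params=params)
        center = X.mean(axis=0)
        direction = np.array([1.0, 1.0]) / np.sqrt(2)
        radius = np.max(np.linalg.norm(X - center, axis=1))
        distances = radius + np.linspace(0.0, 20 * params.length_scale, 40)
        queries = center + distances[:, None] * direction
        _, var = clock.predict(queries)
        assert (np.diff(var) >= -1e-10).all()
        assert abs(var[-1] - params.s2) < 1e-6

    def test_interpolation_limit_as_noise_vanishes(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(size=(10, 1))
        y = np.sin(4 * X[:, 0])
        clock = GPRClock(X=X, y_centered=y, y_offset=0.0,
                         params=KernelParams(s2=1.0, length_scale=0.5, noise=1e-8))
        mu, _ = clock.predict(X)
        # tolerance reflects the near-singular kernel at vanishing noise
        assert np.allclose(mu, y, atol=1e-4)

    def test_dimension_mismatch_rejected(self):
        clock = GPRClock(X=np.zeros((3, 2)), y_centered=np.zeros(3), y_offset=0.0,
                         params=UNIT_PARAMS)
        with pytest.raises(ValueError, match="dimension"):
            clock.predict(np.zeros((1, 3)))


class TestDatasetInterface:
    def test_credible_interval_is_two_sd(self, aging_dataset):
        clock = fit_gpr(aging_dataset, cpgs=aging_dataset.attrs["age_cpgs"][:10],
                        restarts=2, seed=0)
        results = predict_gpr(clock, aging_dataset)
        for pred, interval in results[:20]:
            half = 2.0 * np.sqrt(pred.variance)
            assert interval.lower == pytest.approx(pred.predicted_age - half)
            assert interval.upper == pytest.approx(pred.predicted_age + half)
            assert pred.variance >= 0.0

    def test_ood_course_gets_wider_intervals(self):
        """Samples drifting from the training manifold receive larger
        predictive variance than in-distribution samples."""
        cfg = SimulationConfig(n_samples=80, n_cpgs=60, n_age_cpgs=15, seed=12)
        train = simulate_aging_methylation(cfg)
        course = simulate_reprogramming_course(cfg, [0, 14, 28], 0.02, seed=12,
                                               n_per_day=15)
        clock = fit_gpr(train, restarts=2, seed=12)
        preds = predict_gpr(clock, course)
        mean_var = {
            day: np.mean([p.variance for p, _ in preds if p.group == day])
            for day in (0, 14, 28)
        }
        assert mean_var[0] < mean_var[14] < mean_var[28]
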