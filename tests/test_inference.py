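"""MALA correctness on closed-form targets, diagnostics, and optimization."""

import numpy as np
import pytest

from movegp import (
    ConstantParam,
    MovementModel,
    OptimizerConfig,
    Posterior,
    SamplerConfig,
    Trajectory,
    effective_sample_size,
    mala_step,
    optimize_hyperparameters,
    psrf,
    run_chains,
)
from movegp.inference import _mala_step_cached


def _std_normal_target(dim=1):
    def f(x):
        return -0.5 * float(x @ x), -x

    return f


def _mvn_target(cov):
    prec = np.linalg.inv(cov)

    def f(x):
        return -0.5 * float(x @ prec @ x), -prec @ x

    return f


def _run_mala(target, x0, n, step, seed=0, precond=None):
    rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float)
    logp, grad = target(x)
    out = np.empty((n, len(x)))
    for i in range(n):
        x, logp, grad, _, _ = _mala_step_cached(
            x, logp, grad, target, step, rng, precond
        )
        out[i] = x
    return out


class TestMalaStep:
    def test_flat_target_reduces_to_random_walk(self):
        """With zero gradient the drift vanishes, the Hastings correction is
        symmetric, and every proposal is accepted."""

        def flat(x):
            return 0.0, np.zeros_like(x)

        rng = np.random.default_rng(0)
        x = np.zeros(3)
        accepted = 0
        for _ in range(50):
            x, acc = mala_step(x, flat, step_size=0.5, rng=rng)
            accepted += acc
        assert accepted == 50
        # proposal is exactly x + eps * xi
        rng1, rng2 = np.random.default_rng(1), np.random.default_rng(1)
        x1, _ = mala_step(np.ones(2), flat, 0.3, rng1)
        np.testing.assert_allclose(x1, 1.0 + 0.3 * rng2.standard_normal(2))

    def test_nonfinite_gradient_raises(self):
        def bad(x):
            return 0.0, np.array([np.nan])

        with pytest.raises(FloatingPointError):
            mala_step(np.zeros(1), bad, 0.1, np.random.default_rng(0))

    def test_recovers_standard_normal_moments(self):
        draws = _run_mala(_std_normal_target(), [2.0], n=40000, step=1.2, seed=1)
        x = draws[:, 0]
        ess = effective_sample_size(x[None, :, None]).per_parameter[0]
        se_mean = x.std() / np.sqrt(ess)
        assert abs(x.mean()) < 3 * se_mean
        assert abs(x.var() - 1.0) < 4 * np.sqrt(2 / ess)

    def test_recovers_correlated_gaussian_covariance(self):
        cov = np.array([[1.0, 0.8], [0.8, 2.0]])
        draws = _run_mala(_mvn_target(cov), [0.0, 0.0], n=60000, step=0.7, seed=2)
        emp = np.cov(draws[5000:].T)
        assert np.max(np.abs(emp - cov)) < 0.12


def _tiny_model_and_data(seed=0, n=40, tmax=20.0):
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0, tmax, n))
    nu, eta = 2.0, 1.0
    # stationary OU data, exact transitions
    x = np.empty((n, 2))
    x[0] = eta / np.sqrt(2 * nu) * rng.standard_normal(2)
    for k in range(n - 1):
        dt = t[k + 1] - t[k]
        d = np.exp(-nu * dt)
        x[k + 1] = x[k] * d + eta * np.sqrt((1 - d**2) / (2 * nu)) * rng.standard_normal(2)
    traj = Trajectory("tiny", t, x)
    model = MovementModel(
        latent_sigma=ConstantParam(0.7, sample=True),
        latent_L=ConstantParam(0.7, sample=True),
        sigma_m=ConstantParam(0.05, sample=False),
    )
    return model, [traj]


class TestRunChains:
    def test_thinning_count(self):
        model, data = _tiny_model_and_data()
        cfg = SamplerConfig(n_steps=300, n_burnin=100, thin=20, n_chains=2, seed=3)
        samples = run_chains(model, data, cfg)
        assert samples.n_draws == 10  # (300 - 100) / 20
        assert samples.n_chains == 2

    def test_same_seed_bit_identical(self):
        model, data = _tiny_model_and_data()
        cfg = SamplerConfig(n_steps=200, n_burnin=80, thin=2, n_chains=2, seed=4)
        s1 = run_chains(model, data, cfg)
        s2 = run_chains(model, data, cfg)
        np.testing.assert_array_equal(s1.draws, s2.draws)

    def test_adaptation_reaches_target_acceptance(self):
        """On a well-conditioned 2-parameter posterior the Robbins-Monro
        schedule lands near the MALA-optimal acceptance rate."""
        model, data = _tiny_model_and_data(n=60)
        cfg = SamplerConfig(
            n_steps=4000, n_burnin=2000, thin=1, n_chains=1, seed=5,
            target_acceptance=0.574,
        )
        samples = run_chains(model, data, cfg)
        assert abs(samples.acceptance[0] - 0.574) < 0.1

    def test_save_load_round_trip(self, tmp_path):
        model, data = _tiny_model_and_data()
        cfg = SamplerConfig(n_steps=120, n_burnin=40, thin=4, n_chains=2, seed=6)
        s1 = run_chains(model, data, cfg)
        path = str(tmp_path / "samples.npz")
        s1.save(path)
        from movegp import PosteriorSamples

        s2 = PosteriorSamples.load(path)
        np.testing.assert_array_equal(s1.draws, s2.draws)
        assert s2.index == s1.index
        assert s2.config == s1.config


class TestPsrf:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((4, 10000, 3))
        r = psrf(a)
        assert np.all(r.per_parameter >= 0.99)
        assert np.all(r.per_parameter <= 1.02)

    def test_offset_chain_flagged(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal((4, 500, 1))
        a[0] += 100.0
        assert psrf(a).max > 1.5

    def test_matches_arviz_identity_method(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(9)
        a = rng.standard_normal((4, 2000, 2)) + 0.1 * rng.standard_normal((4, 1, 2))
        mine = psrf(a).per_parameter
        theirs = np.stack(
            [
                float(arviz.rhat(arviz.convert_to_dataset(a[:, :, j]), method="identity")["x"])
                for j in range(2)
            ]
        )
        # arviz splits chains in half; agreement is approximate but tight here
        np.testing.assert_allclose(mine, theirs, atol=0.01)

    def test_degenerate_chain_rejected(self):
        with pytest.raises(ValueError):
            psrf(np.zeros((2, 100, 1)))


class TestEffectiveSampleSize:
    def _ar1(self, rho, n, m=1, seed=0):
        rng = np.random.default_rng(seed)
        x = np.zeros((m, n))
        innov_sd = np.sqrt(1 - rho**2)
        x[:, 0] = rng.standard_normal(m)
        for i in range(1, n):
            x[:, i] = rho * x[:, i - 1] + innov_sd * rng.standard_normal(m)
        return x[:, :, None]

    def test_iid_draws_ess_near_n(self):
        rng = np.random.default_rng(10)
        a = rng.standard_normal((2, 5000, 1))
        ess = effective_sample_size(a).per_parameter[0]
        assert 0.8 * 10000 <= ess <= 10000

    def test_nearly_constant_chain_tiny_ess(self):
        ess = effective_sample_size(self._ar1(0.999, 20000)).per_parameter[0]
        assert ess < 100

    def test_ar1_matches_analytic_rate(self):
        rho, n = 0.9, 100000
        ess = effective_sample_size(self._ar1(rho, n, seed=11)).per_parameter[0]
        expected = n * (1 - rho) / (1 + rho)
        assert abs(ess - expected) / expected < 0.2

    def test_matches_arviz(self):
        arviz = pytest.importorskip("arviz")
        a = self._ar1(0.8, 20000, m=2, seed=12)
        mine = effective_sample_size(a).per_parameter[0]
        theirs = float(arviz.ess(arviz.convert_to_dataset(a[:, :, 0]))["x"])
        assert abs(mine - theirs) / theirs < 0.2


class TestOptimizer:
    def test_recovers_stationary_kernel_parameters(self):
        """MAP fit on data simulated from a known stationary OU model
        recovers amplitude and lengthscale within 25% at n=500."""
        model, data = _tiny_model_and_data(seed=13, n=500, tmax=100.0)
        theta, trace, _ = optimize_hyperparameters(
            model, data, OptimizerConfig(learning_rate=0.05, n_iters=400)
        )
        sigma_hat = np.exp(theta["sigma.log_const"])
        L_hat = np.exp(theta["L.log_const"])
        # truth: nu=2, eta=1 -> sigma = sqrt(eta^2/(2 nu)) = 0.5, L = 0.5
        assert abs(sigma_hat - 0.5) / 0.5 < 0.25
        assert abs(L_hat - 0.5) / 0.5 < 0.25

    def test_matches_grid_search_on_one_parameter(self):
        model, data = _tiny_model_and_data(seed=14, n=80)
        model.latent_L = ConstantParam(0.5, sample=False)
        post = Posterior(model, data)

        grid = np.linspace(-2, 2, 401)
        vals = [post.value(np.array([g])) for g in grid]
        oracle = grid[int(np.argmax(vals))]
        theta, _, _ = optimize_hyperparameters(
            model, data, OptimizerConfig(learning_rate=0.05, n_iters=300)
        )
        assert abs(theta["sigma.log_const"] - oracle) < 0.02

    def test_loss_stays_flat_from_optimal_start(self):
        model, data = _tiny_model_and_data(seed=15, n=60)
        theta, trace, state = optimize_hyperparameters(
            model, data, OptimizerConfig(learning_rate=0.05, n_iters=300)
        )
        model2 = state.apply_to(model)
        _, trace2, _ = optimize_hyperparameters(
            model2, data, OptimizerConfig(learning_rate=0.01, n_iters=50)
        )
        assert np.max(trace2) <= trace2[0] + 0.1

    def test_empty_data_rejected(self):
        model, _ = _tiny_model_and_data()
        with pytest.raises(ValueError):
            optimize_hyperparameters(model, [])
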