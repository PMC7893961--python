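"""Latent realization, the data likelihood, and the joint log posterior."""

import numpy as np
import pytest
from scipy.linalg import cholesky
from scipy.stats import multivariate_normal

from movegp import (
    ConstantParam,
    LatentFunction,
    ModelState,
    MovementModel,
    PeriodicKernelParams,
    Posterior,
    QuasiPeriodicKernelParams,
    StationaryMatern12Params,
    Trajectory,
    log_data_likelihood,
    log_posterior,
    realize_latent,
)

_LOG2PI = np.log(2 * np.pi)


def _toy_trajectory(n=20, seed=0, tmax=48.0):
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0, tmax, n))
    return Trajectory("toy", t, rng.normal(size=(n, 2)))


def _small_model(seed=0, sample_scalars=True):
    lat = LatentFunction(
        support_times=np.linspace(0, 24, 8, endpoint=False),
        mu=0.1,
        kernel=PeriodicKernelParams(a=0.5, l=1.2, P=24.0),
        transform="exponential",
        sample_mu=sample_scalars,
        free_kernel_params=("a", "l") if sample_scalars else (),
    )
    return MovementModel(
        latent_sigma=lat,
        latent_L=ConstantParam(0.5, sample=sample_scalars),
        sigma_m=ConstantParam(0.1, sample=sample_scalars),
    )


class TestRealizeLatent:
    def test_zero_whitened_gives_exp_of_mean(self):
        lat = LatentFunction(
            support_times=np.linspace(0, 10, 6),
            mu=0.0,
            kernel=StationaryMatern12Params(sigma_k=1.0, L=3.0),
        )
        vals = realize_latent(lat, np.linspace(0, 10, 17))
        np.testing.assert_allclose(vals, 1.0)

    def test_interpolates_support_values_exactly(self):
        rng = np.random.default_rng(5)
        st = np.linspace(0, 10, 7)
        lat = LatentFunction(
            support_times=st,
            mu=0.4,
            kernel=StationaryMatern12Params(sigma_k=0.8, L=4.0),
            whitened=rng.standard_normal(7),
        )
        D = np.abs(st[:, None] - st[None, :])
        K = lat.kernel.cov_from_absdiff(D)
        K += 1e-6 * np.mean(np.diag(K)) * np.eye(7)
        expected = np.exp(lat.mu + cholesky(K, lower=True) @ lat.whitened)
        # interpolation is exact up to the relative support jitter (1e-6)
        np.testing.assert_allclose(realize_latent(lat, st), expected, rtol=1e-5)

    def test_matches_direct_gp_conditional_oracle(self):
        # independent dense-grid conditional mean via np.linalg.solve
        rng = np.random.default_rng(6)
        st = np.linspace(0, 24, 30)
        kern = PeriodicKernelParams(a=0.7, l=1.5, P=24.0)
        w = rng.standard_normal(30)
        lat = LatentFunction(
            support_times=st, mu=0.2, kernel=kern, whitened=w,
            transform="identity",
        )
        te = rng.uniform(0, 24, 25)
        D_ss = np.abs(st[:, None] - st[None, :])
        K_ss = kern.cov_from_absdiff(D_ss)
        K_ss += 1e-6 * np.mean(np.diag(K_ss)) * np.eye(30)
        f_supp = 0.2 + np.linalg.cholesky(K_ss) @ w
        K_es = kern.cov_from_absdiff(np.abs(te[:, None] - st[None, :]))
        oracle = 0.2 + K_es @ np.linalg.solve(K_ss, f_supp - 0.2)
        np.testing.assert_allclose(realize_latent(lat, te), oracle, rtol=1e-8)


class TestLogDataLikelihood:
    def test_single_point_standard_normal(self):
        traj = Trajectory("p", [0.0], [[0.0, 0.0]])
        # sigma(t)^2 + sigma_m^2 = 1
        ll = log_data_likelihood(
            traj, sigma_t=[0.8], L_t=[1.0], mean_t=[[0.0, 0.0]],
            sigma_m=0.6, jitter=0.0,
        )
        assert ll == pytest.approx(2 * (-0.5 * _LOG2PI), abs=1e-12)

    def test_measurement_noise_lowers_density_at_mean(self):
        traj = Trajectory("p", [0.0, 1.0], [[0.0, 0.0], [0.0, 0.0]])
        args = dict(sigma_t=[1.0, 1.0], L_t=[1.0, 1.0], mean_t=np.zeros((2, 2)))
        assert log_data_likelihood(traj, sigma_m=0.5, **args) < log_data_likelihood(
            traj, sigma_m=0.0, **args
        )

    def test_matches_generic_mvn_logpdf(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            n = rng.integers(2, 12)
            t = np.sort(rng.uniform(0, 10, n))
            s = rng.uniform(0.5, 2.0, n)
            L = rng.uniform(0.5, 3.0, n)
            mean = rng.normal(size=(n, 2))
            x = rng.normal(size=(n, 2))
            sm = 0.3
            traj = Trajectory("p", t, x)
            from movegp import nonstationary_matern12_cov, NonStationaryInputs

            K = nonstationary_matern12_cov(
                NonStationaryInputs(t, s, L), NonStationaryInputs(t, s, L)
            ) + sm**2 * np.eye(n)
            oracle = sum(
                multivariate_normal(mean[:, c], K).logpdf(x[:, c]) for c in range(2)
            )
            mine = log_data_likelihood(traj, s, L, mean, sm, jitter=0.0)
            assert mine == pytest.approx(oracle, abs=1e-8)


class TestLogPosterior:
    def test_zero_whitened_prior_constant(self):
        traj = _toy_trajectory()
        model = _small_model(sample_scalars=False)
        post = Posterior(model, [traj])
        x0 = post.initial_vector()  # all whitened zeros, no scalar entries
        assert len(x0) == 8
        sigma_t = realize_latent(model.latent_sigma, traj.times)
        data_ll = log_data_likelihood(
            traj,
            sigma_t,
            np.full(len(traj), model.latent_L.value),
            np.zeros((len(traj), 2)),
            model.sigma_m.value,
        )
        lp = log_posterior(x0, [traj], model)
        assert lp == pytest.approx(post.value(x0), rel=1e-12)
        assert lp - data_ll == pytest.approx(8 * (-0.5 * _LOG2PI), abs=1e-9)

    def test_duplicated_segment_adds_its_own_likelihood(self):
        traj = _toy_trajectory(n=15)
        model = _small_model()
        post1 = Posterior(model, [traj])
        post2 = Posterior(model, [traj, traj])
        x = post1.initial_vector()
        sigma_t = realize_latent(model.latent_sigma, traj.times)
        seg_ll = log_data_likelihood(
            traj,
            sigma_t,
            np.full(len(traj), model.latent_L.value),
            np.zeros((len(traj), 2)),
            model.sigma_m.value,
        )
        assert post2.value(x) - post1.value(x) == pytest.approx(seg_ll, rel=1e-10)

    def test_segment_order_invariance(self):
        t1 = _toy_trajectory(n=12, seed=1)
        t2 = _toy_trajectory(n=9, seed=2)
        model = _small_model()
        x = Posterior(model, [t1, t2]).initial_vector()
        a = Posterior(model, [t1, t2]).value(x)
        b = Posterior(model, [t2, t1]).value(x)
        assert a == pytest.approx(b, rel=1e-12)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            Posterior(_small_model(), [])

    def test_whitened_matches_direct_hierarchical_density(self):
        """exp(logpost) in w is proportional to the direct hierarchical
        density in f = mu + chol(K) w: their log difference is constant."""
        rng = np.random.default_rng(8)
        traj = _toy_trajectory(n=20, seed=3)
        model = _small_model(sample_scalars=False)
        post = Posterior(model, [traj])
        lat = model.latent_sigma
        st = lat.support_times
        D = np.abs(st[:, None] - st[None, :])
        K = lat.kernel.cov_from_absdiff(D)
        K += 1e-6 * np.mean(np.diag(K)) * np.eye(len(st))
        C = cholesky(K, lower=True)

        def direct(w):
            f_supp = lat.mu + C @ w
            # realize at data times through the same conditional interpolation
            K_es = lat.kernel.cov_from_absdiff(
                np.abs(traj.times[:, None] - st[None, :])
            )
            sigma_t = np.exp(lat.mu + K_es @ np.linalg.solve(K, f_supp - lat.mu))
            ll = log_data_likelihood(
                traj,
                sigma_t,
                np.full(len(traj), model.latent_L.value),
                np.zeros((len(traj), 2)),
                model.sigma_m.value,
            )
            prior = multivariate_normal(np.full(len(st), lat.mu), K).logpdf(f_supp)
            return ll + prior

        diffs = []
        for _ in range(6):
            w = rng.standard_normal(len(st))
            diffs.append(post.value(w) - direct(w))
        assert np.std(diffs) < 1e-8

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(9)
        traj = _toy_trajectory(n=18, seed=4)
        lat_L = LatentFunction(
            support_times=np.linspace(0, 48, 5),
            mu=-0.5,
            kernel=QuasiPeriodicKernelParams(a=0.3, lam=30.0, l=1.0, P=24.0),
            transform="exponential",
            sample_mu=True,
            free_kernel_params=("a", "l", "lam"),
        )
        mean_lat = lambda: LatentFunction(
            support_times=np.linspace(0, 48, 5),
            mu=0.0,
            kernel=StationaryMatern12Params(sigma_k=1.0, L=10.0),
            transform="identity",
            free_kernel_params=("sigma_k", "L"),
        )
        model = MovementModel(
            latent_sigma=_small_model().latent_sigma,
            latent_L=lat_L,
            latent_mean=(mean_lat(), mean_lat()),
            sigma_m=ConstantParam(0.2, sample=True),
        )
        post = Posterior(model, [traj])
        x0 = post.initial_vector() + 0.3 * rng.standard_normal(
            len(post.initial_vector())
        )
        _, g = post.value_and_grad(x0)
        eps = 1e-5
        for i in range(len(x0)):
            xp, xm = x0.copy(), x0.copy()
            xp[i] += eps
            xm[i] -= eps
            fd = (post.value(xp) - post.value(xm)) / (2 * eps)
            assert abs(g[i] - fd) / (abs(fd) + 1e-8) < 1e-4


class TestModelState:
    def test_round_trip_through_structured_model(self):
        model = _small_model()
        state = ModelState.from_model(model)
        rng = np.random.default_rng(10)
        state2 = state.with_vector(state.vector + rng.standard_normal(len(state)))
        model2 = state2.apply_to(model)
        state3 = ModelState.from_model(model2)
        np.testing.assert_allclose(state3.vector, state2.vector, rtol=1e-12)
        assert state3.index == state2.index

    def test_flat_names_cover_all_coordinates(self):
        state = ModelState.from_model(_small_model())
        assert len(state.flat_names()) == len(state)
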