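"""Hierarchical movement model: latent functions, likelihood and posterior.

The observation model is a 2-D Gaussian process with a non-stationary
Matérn 1/2 kernel: each coordinate is a univariate GP sharing the same
time-varying amplitude sigma(t), lengthscale L(t) and measurement noise
sigma_m, with its own mean function.  sigma(t) and L(t) are themselves
lower-level GPs represented at a small number of support points and pushed
through an exponential transform to stay positive; the mean function is a
zero-mean GP per coordinate.

Sampling operates on *whitened* coordinates: each latent is written
``f = mu + chol(K) @ w`` with ``w`` a priori standard normal, which
decorrelates the posterior for gradient-based MCMC.  The log posterior and
its exact gradient (with respect to every whitened vector, every sampled
constant on the log scale, the latent prior means, and the log kernel
hyperparameters) are computed in closed form; hyperparameter directions use
a forward-mode differential of the Cholesky factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
import scipy.linalg as sla

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "LatentFunction",
    "ConstantParam",
    "MovementModel",
    "ModelState",
    "Posterior",
    "realize_latent",
    "log_data_likelihood",
    "log_posterior",
    "log_posterior_and_grad",
]

_LOG2PI = float(np.log(2.0 * np.pi))


def cholesky(a, lower=True):
    return sla.cholesky(a, lower=lower, check_finite=False)


def cho_factor(a, lower=True):
    return sla.cho_factor(a, lower=lower, check_finite=False)


def cho_solve(c_and_lower, b):
    return sla.cho_solve(c_and_lower, b, check_finite=False)


def solve_triangular(a, b, lower=True):
    return sla.solve_triangular(a, b, lower=lower, check_finite=False)


# ----------------------------------------------------------------------
# Data containers
# ----------------------------------------------------------------------


@dataclass
class Trajectory:
    """One individual's timestamped 2-D positions or velocities."""

    individual_id: str
    times: np.ndarray
    values: np.ndarray
    value_kind: str = "position"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 2:
            raise ValueError("values must be an (n, 2) array")
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) < 1:
            raise ValueError("trajectory needs at least one fix")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries in trajectory")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.value_kind not in ("position", "velocity"):
            raise ValueError("value_kind must be 'position' or 'velocity'")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class LatentFunction:
    """A lower-level GP over time, represented at support points.

    ``mu`` is the constant prior mean (on the pre-transform scale), ``kernel``
    one of the kernel parameter types, ``whitened`` the sampled standard
    normal vector ``w`` such that the support values are
    ``mu + chol(K_ss) @ w``.  ``transform='exponential'`` maps the latent to
    strictly positive values (used for sigma and L); the mean function uses
    the identity.  ``free_kernel_params`` names the kernel parameters sampled
    on the log scale; ``sample_mu`` adds ``mu`` itself to the sampled state.
    """

    support_times: np.ndarray
    mu: float
    kernel: object
    whitened: Optional[np.ndarray] = None
    transform: str = "exponential"
    sample_mu: bool = False
    free_kernel_params: tuple = ()
    hyper_group: Optional[str] = None  # latents sharing this name share
    # their sampled kernel hyperparameters (and mu) in the state vector
    extrapolation_margin: float = 0.1  # fraction of support span

    def __post_init__(self) -> None:
        self.support_times = np.asarray(self.support_times, dtype=float)
        if len(self.support_times) < 2:
            raise ValueError("need at least 2 support points")
        if not np.all(np.diff(self.support_times) > 0):
            raise ValueError("support_times must be strictly increasing")
        if self.whitened is None:
            self.whitened = np.zeros(len(self.support_times))
        self.whitened = np.asarray(self.whitened, dtype=float)
        if len(self.whitened) != len(self.support_times):
            raise ValueError("whitened vector length must match support points")
        if self.transform not in ("exponential", "identity"):
            raise ValueError("transform must be 'exponential' or 'identity'")
        if "P" in self.free_kernel_params:
            raise ValueError("the period P is a fixed structural choice, not sampled")

    @property
    def m(self) -> int:
        return len(self.support_times)


@dataclass
class ConstantParam:
    """A static, strictly positive movement parameter, optionally sampled on the log scale."""

    value: float
    sample: bool = True

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("constant parameters must be strictly positive")


LatentOrConst = Union[LatentFunction, ConstantParam]


@dataclass
class MovementModel:
    """The full hierarchy: which movement parameters vary, and their priors.

    ``latent_sigma``/``latent_L`` are either :class:`LatentFunction` (dynamic)
    or :class:`ConstantParam` (static); ``latent_mean`` is an (x, y) pair of
    identity-transform latents or ``None`` for a fixed zero mean.  ``sigma_m``
    is the measurement noise standard deviation.  ``theta_priors`` maps state
    entry names to (mean, sd) of independent normal priors; unlisted sampled
    scalars default to N(0, 2^2) on their (log) scale.
    """

    latent_sigma: LatentOrConst
    latent_L: LatentOrConst
    latent_mean: Optional[tuple] = None
    sigma_m: Union[ConstantParam, float] = 0.0
    theta_priors: dict = field(default_factory=dict)
    default_prior_sd: float = 2.0

    def __post_init__(self) -> None:
        if isinstance(self.sigma_m, ConstantParam):
            if self.sigma_m.value < 0:
                raise ValueError("sigma_m must be non-negative")
        elif self.sigma_m < 0:
            raise ValueError("sigma_m must be non-negative")
        if self.latent_mean is not None:
            if len(self.latent_mean) != 2:
                raise ValueError("latent_mean must be an (x, y) pair")
            for lf in self.latent_mean:
                if lf.transform != "identity":
                    raise ValueError("mean latents use the identity transform")

    def prior_for(self, name: str) -> tuple:
        return self.theta_priors.get(name, (0.0, self.default_prior_sd))

    def blocks(self) -> list:
        """(name, component) pairs in canonical state order."""
        out = [("sigma", self.latent_sigma), ("L", self.latent_L)]
        if self.latent_mean is not None:
            out.append(("mean_x", self.latent_mean[0]))
            out.append(("mean_y", self.latent_mean[1]))
        return out


# ----------------------------------------------------------------------
# Flat state vector
# ----------------------------------------------------------------------


class ModelState:
    """Flat vector of all sampled unknowns with a name -> slice index.

    Round-trips losslessly between the flat vector and the structured model:
    whitened vectors are stored as-is, constants and kernel hyperparameters
    on the log scale, latent prior means on their natural scale.
    """

    def __init__(self, vector: np.ndarray, index: dict):
        self.vector = np.asarray(vector, dtype=float)
        self.index = dict(index)

    @classmethod
    def from_model(cls, model: MovementModel) -> "ModelState":
        parts: list = []
        index: dict = {}
        pos = 0

        def push(name: str, arr: np.ndarray) -> None:
            nonlocal pos
            arr = np.atleast_1d(np.asarray(arr, dtype=float))
            index[name] = slice(pos, pos + arr.size)
            parts.append(arr)
            pos += arr.size

        for bname, comp in model.blocks():
            if isinstance(comp, LatentFunction):
                push(f"{bname}.w", comp.whitened)
                prefix = comp.hyper_group or bname
                if comp.sample_mu and f"{prefix}.mu" not in index:
                    push(f"{prefix}.mu", comp.mu)
                for p in comp.free_kernel_params:
                    if f"{prefix}.log_{p}" not in index:
                        push(f"{prefix}.log_{p}", comp.kernel.log_value(p))
            elif isinstance(comp, ConstantParam):
                if comp.sample:
                    push(f"{bname}.log_const", np.log(comp.value))
        if isinstance(model.sigma_m, ConstantParam) and model.sigma_m.sample:
            push("log_sigma_m", np.log(model.sigma_m.value))
        vec = np.concatenate(parts) if parts else np.zeros(0)
        return cls(vec, index)

    def get(self, name: str) -> np.ndarray:
        return self.vector[self.index[name]]

    def to_dict(self) -> dict:
        return {name: self.vector[sl].copy() for name, sl in self.index.items()}

    def with_vector(self, vector: np.ndarray) -> "ModelState":
        if len(vector) != len(self.vector):
            raise ValueError("vector length mismatch")
        return ModelState(vector, self.index)

    def apply_to(self, model: MovementModel) -> MovementModel:
        """Return a copy of ``model`` with this state's values written back."""
        new_blocks = {}
        for bname, comp in model.blocks():
            if isinstance(comp, LatentFunction):
                prefix = comp.hyper_group or bname
                comp = replace(comp)
                comp.whitened = self.get(f"{bname}.w").copy()
                if comp.sample_mu:
                    comp.mu = float(self.get(f"{prefix}.mu")[0])
                if comp.free_kernel_params:
                    updates = {
                        p: float(self.get(f"{prefix}.log_{p}")[0])
                        for p in comp.free_kernel_params
                    }
                    comp.kernel = comp.kernel.replace_log(**updates)
            elif isinstance(comp, ConstantParam) and comp.sample:
                comp = ConstantParam(
                    float(np.exp(self.get(f"{bname}.log_const")[0])), sample=True
                )
            new_blocks[bname] = comp
        sigma_m = model.sigma_m
        if isinstance(sigma_m, ConstantParam) and sigma_m.sample:
            sigma_m = ConstantParam(
                float(np.exp(self.get("log_sigma_m")[0])), sample=True
            )
        mean = None
        if model.latent_mean is not None:
            mean = (new_blocks["mean_x"], new_blocks["mean_y"])
        return MovementModel(
            latent_sigma=new_blocks["sigma"],
            latent_L=new_blocks["L"],
            latent_mean=mean,
            sigma_m=sigma_m,
            theta_priors=model.theta_priors,
            default_prior_sd=model.default_prior_sd,
        )

    def flat_names(self) -> list:
        """One name per scalar entry, vectors expanded with [i] suffixes."""
        out = []
        for name, sl in self.index.items():
            n = sl.stop - sl.start
            if n == 1:
                out.append(name)
            else:
                out.extend(f"{name}[{i}]" for i in range(n))
        return out

    def __len__(self) -> int:
        return len(self.vector)


# ----------------------------------------------------------------------
# Latent realization
# ----------------------------------------------------------------------


def _support_chol(latent: LatentFunction) -> np.ndarray:
    D = np.abs(latent.support_times[:, None] - latent.support_times[None, :])
    K = latent.kernel.cov_from_absdiff(D)
    jit = 1e-6 * float(np.mean(np.diag(K)))
    return cholesky(K + jit * np.eye(latent.m), lower=True)


def realize_latent(latent: LatentFunction, eval_times: np.ndarray) -> np.ndarray:
    """Latent function values at ``eval_times``.

    Support values are ``mu + chol(K_ss + jitter) @ w``; values elsewhere are
    the noiseless GP conditional mean given the support values
    (subset-of-regressors interpolation); the exponential transform, when
    configured, is applied last.  Deterministic given ``(w, kernel)``.
    """
    eval_times = np.asarray(eval_times, dtype=float)
    lo, hi = latent.support_times[0], latent.support_times[-1]
    margin = latent.extrapolation_margin * (hi - lo)
    if np.any(eval_times < lo - margin) or np.any(eval_times > hi + margin):
        logger.warning(
            "evaluating latent outside support range [%g, %g] + margin", lo, hi
        )
    C = _support_chol(latent)
    u = C @ latent.whitened  # f_supp - mu
    D_es = np.abs(eval_times[:, None] - latent.support_times[None, :])
    K_es = latent.kernel.cov_from_absdiff(D_es)
    z = cho_solve((C, True), u)
    f = latent.mu + K_es @ z
    if latent.transform == "exponential":
        return np.exp(f)
    return f


# ----------------------------------------------------------------------
# Data likelihood
# ----------------------------------------------------------------------


def _nonstat_cov_from_parts(
    D: np.ndarray, sigma: np.ndarray, L: np.ndarray
) -> tuple:
    """Non-stationary Matérn 1/2 on one time grid, plus reusable factors."""
    L2 = L**2
    s2 = sigma**2
    S = L2[:, None] + L2[None, :]
    sqS = np.sqrt(S)
    pref = np.sqrt(2.0 * (s2[:, None] * s2[None, :]) * (L[:, None] * L[None, :]) / S)
    K = pref * np.exp(-np.sqrt(2.0) * D / sqS)
    return K, S


def log_data_likelihood(
    traj: Trajectory,
    sigma_t: np.ndarray,
    L_t: np.ndarray,
    mean_t: np.ndarray,
    sigma_m: float,
    jitter: float = 1e-8,
) -> float:
    """Gaussian log likelihood of a trajectory segment.

    Both coordinates share the covariance ``K_NS + sigma_m^2 I`` (plus a tiny
    fixed diagonal jitter) and have per-coordinate means; the result is the
    sum of the two univariate-GP log densities.
    """
    sigma_t = np.asarray(sigma_t, dtype=float)
    L_t = np.asarray(L_t, dtype=float)
    mean_t = np.asarray(mean_t, dtype=float)
    n = len(traj)
    if not (len(sigma_t) == len(L_t) == len(mean_t) == n):
        raise ValueError("sigma_t, L_t, mean_t must align with traj.times")
    D = np.abs(traj.times[:, None] - traj.times[None, :])
    K, _ = _nonstat_cov_from_parts(D, sigma_t, L_t)
    Sig = K + (sigma_m**2 + jitter) * np.eye(n)
    c, low = cho_factor(Sig, lower=True)
    r = traj.values - mean_t
    alpha = cho_solve((c, low), r)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    quad = float(np.sum(r * alpha))
    return -0.5 * quad - logdet - n * _LOG2PI


# ----------------------------------------------------------------------
# Posterior with exact gradient
# ----------------------------------------------------------------------


def _phi(A: np.ndarray) -> np.ndarray:
    """Lower triangle with halved diagonal (Cholesky differential operator)."""
    out = np.tril(A)
    out[np.diag_indices_from(out)] *= 0.5
    return out


class Posterior:
    """Joint unnormalized log posterior over a set of trajectory segments.

    Segments (and individuals) are conditionally independent given the shared
    latent functions, so the data term is a sum over segments.  The whitened
    vectors carry standard normal priors — the whitened equivalent of the GP
    priors on the latents — and every sampled scalar carries an independent
    normal prior on its (log) scale.

    Time-difference matrices are precomputed once; each evaluation then costs
    one Cholesky per segment plus the latent interpolation products.
    """

    def __init__(
        self,
        model: MovementModel,
        segments: list,
        jitter: float = 1e-8,
        support_jitter_rel: float = 1e-6,
    ):
        if not segments:
            raise ValueError("empty data: need at least one trajectory segment")
        self.model = model
        self.segments = list(segments)
        self.jitter = jitter
        self.support_jitter_rel = support_jitter_rel
        self.template = ModelState.from_model(model)

        self.all_times = np.concatenate([s.times for s in self.segments])
        self.n_all = len(self.all_times)
        self.seg_slices = []
        pos = 0
        for s in self.segments:
            self.seg_slices.append(slice(pos, pos + len(s)))
            pos += len(s)
        self.seg_D = [
            np.abs(s.times[:, None] - s.times[None, :]) for s in self.segments
        ]
        self.seg_values = [s.values for s in self.segments]

        # per-latent cached kernel feature matrices (time grids never change)
        self._lat_cache = {}
        for bname, comp in model.blocks():
            if isinstance(comp, LatentFunction):
                st = comp.support_times
                D_ss = np.abs(st[:, None] - st[None, :])
                D_es = np.abs(self.all_times[:, None] - st[None, :])
                self._lat_cache[bname] = (
                    comp.kernel.make_features(D_ss),
                    comp.kernel.make_features(D_es),
                )

    # -- latent block evaluation ---------------------------------------

    def _eval_block(self, bname: str, comp: LatentFunction, state: ModelState):
        F_ss, F_es = self._lat_cache[bname]
        prefix = comp.hyper_group or bname
        w = state.get(f"{bname}.w")
        mu = (
            float(state.get(f"{prefix}.mu")[0]) if comp.sample_mu else comp.mu
        )
        kernel = comp.kernel
        if comp.free_kernel_params:
            updates = {
                p: float(state.get(f"{prefix}.log_{p}")[0])
                for p in comp.free_kernel_params
            }
            kernel = kernel.replace_log(**updates)
        K_ss = kernel.cov_from_features(F_ss)
        jit = self.support_jitter_rel * float(np.mean(np.diag(K_ss)))
        Kj = K_ss + jit * np.eye(len(K_ss))
        C = cholesky(Kj, lower=True)
        u = C @ w
        z = cho_solve((C, True), u)
        K_es = kernel.cov_from_features(F_es)
        f = mu + K_es @ z
        v = np.exp(f) if comp.transform == "exponential" else f
        cache = dict(
            kernel=kernel, C=C, u=u, z=z, K_ss=K_ss, jit=jit, K_es=K_es,
            f=f, v=v, w=w, mu=mu, F_ss=F_ss, F_es=F_es,
        )
        return v, cache

    def _block_grads(self, comp: LatentFunction, cache: dict, g_v: np.ndarray):
        """Gradients of the data term wrt this block's state entries.

        ``g_v`` is dlogp/d(latent values at all data times).
        """
        h = g_v * cache["v"] if comp.transform == "exponential" else g_v
        C, K_es, z = cache["C"], cache["K_es"], cache["z"]
        # f = mu + K_es K_ss^{-1} C w
        Kes_t_h = K_es.T @ h
        grads = {"w": C.T @ cho_solve((C, True), Kes_t_h)}
        if comp.sample_mu:
            grads["mu"] = np.array([float(np.sum(h))])
        kernel = cache["kernel"]
        for p in comp.free_kernel_params:
            dK_ss = kernel.cov_grad_log_features(p, cache["F_ss"], cache["K_ss"])
            if p in ("a", "sigma_k"):
                dK_ss = dK_ss + cache["jit"] * np.eye(len(dK_ss))
            dK_es = kernel.cov_grad_log_features(p, cache["F_es"], K_es)
            # forward-mode Cholesky differential: dC = C Phi(C^{-1} dK C^{-T})
            tmp = solve_triangular(C, dK_ss, lower=True)
            tmp = solve_triangular(C, tmp.T, lower=True).T
            dC = C @ _phi(tmp)
            du = dC @ cache["w"]
            dz = cho_solve((C, True), du - dK_ss @ z)
            df = dK_es @ z + K_es @ dz
            grads[f"log_{p}"] = np.array([float(np.dot(h, df))])
        return grads

    # -- main evaluation ------------------------------------------------

    def value_and_grad(self, x: np.ndarray) -> tuple:
        """Log posterior and its gradient at the flat state vector ``x``.

        Numerically hopeless states (overflowing transforms, indefinite
        covariances from extreme proposals) return ``-inf`` with a zero
        gradient so the sampler can reject them.
        """
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            try:
                return self._value_and_grad(x)
            except np.linalg.LinAlgError:
                return -np.inf, np.zeros(len(self.template.vector))

    def _value_and_grad(self, x: np.ndarray) -> tuple:
        state = self.template.with_vector(np.asarray(x, dtype=float))
        model = self.model
        grad = np.zeros_like(state.vector)

        # --- realize latents / constants at all data times
        block_caches = {}
        vals = {}
        for bname, comp in model.blocks():
            if isinstance(comp, LatentFunction):
                v, cache = self._eval_block(bname, comp, state)
                vals[bname] = v
                block_caches[bname] = (comp, cache)
            else:
                c = (
                    float(np.exp(state.get(f"{bname}.log_const")[0]))
                    if comp.sample
                    else comp.value
                )
                vals[bname] = np.full(self.n_all, c)
        sigma_all, L_all = vals["sigma"], vals["L"]
        if not all(np.all(np.isfinite(v)) for v in vals.values()):
            return -np.inf, grad
        if model.latent_mean is not None:
            mean_all = np.column_stack([vals["mean_x"], vals["mean_y"]])
        else:
            mean_all = np.zeros((self.n_all, 2))
        sm_sampled = isinstance(model.sigma_m, ConstantParam) and model.sigma_m.sample
        if sm_sampled:
            sigma_m = float(np.exp(state.get("log_sigma_m")[0]))
        elif isinstance(model.sigma_m, ConstantParam):
            sigma_m = model.sigma_m.value
        else:
            sigma_m = float(model.sigma_m)

        # --- data term, accumulating dlogp/d(latent values at data times)
        logp = 0.0
        g_sigma = np.zeros(self.n_all)
        g_L = np.zeros(self.n_all)
        g_mean = np.zeros((self.n_all, 2))
        g_sigma_m = 0.0
        sqrt2 = np.sqrt(2.0)
        for D, sl, xv in zip(self.seg_D, self.seg_slices, self.seg_values):
            n = D.shape[0]
            s = sigma_all[sl]
            L = L_all[sl]
            K, S = _nonstat_cov_from_parts(D, s, L)
            Sig = K + (sigma_m**2 + self.jitter) * np.eye(n)
            c, low = cho_factor(Sig, lower=True)
            r = xv - mean_all[sl]
            sol = cho_solve((c, low), np.concatenate([r, np.eye(n)], axis=1))
            alpha = sol[:, :2]
            Sinv = sol[:, 2:]
            logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
            logp += -0.5 * float(np.sum(r * alpha)) - logdet - n * _LOG2PI
            G = 0.5 * (alpha @ alpha.T) - Sinv
            GK = G * K
            g_sigma[sl] += 2.0 * GK.sum(axis=1) / s
            Sm32 = 1.0 / (S * np.sqrt(S))
            g_L[sl] += 2.0 * (
                GK.sum(axis=1) / (2.0 * L)
                - L * (GK / S).sum(axis=1)
                + sqrt2 * L * (GK * D * Sm32).sum(axis=1)
            )
            g_mean[sl] += alpha
            g_sigma_m += 2.0 * sigma_m * float(np.trace(G))

        # --- scatter data-term gradients into state coordinates
        for bname, comp in model.blocks():
            g_v = {"sigma": g_sigma, "L": g_L}.get(bname)
            if g_v is None:
                g_v = g_mean[:, 0] if bname == "mean_x" else g_mean[:, 1]
            if bname in block_caches:
                comp_, cache = block_caches[bname]
                prefix = comp.hyper_group or bname
                for suffix, g in self._block_grads(comp_, cache, g_v).items():
                    owner = bname if suffix == "w" else prefix
                    grad[state.index[f"{owner}.{suffix}"]] += g
            elif isinstance(comp, ConstantParam) and comp.sample:
                cval = vals[bname][0]
                grad[state.index[f"{bname}.log_const"]] += float(np.sum(g_v)) * cval
        if sm_sampled:
            grad[state.index["log_sigma_m"]] += g_sigma_m * sigma_m

        # --- priors
        for name, sl in state.index.items():
            v = state.vector[sl]
            if name.endswith(".w"):
                logp += -0.5 * float(v @ v) - 0.5 * v.size * _LOG2PI
                grad[sl] += -v
            else:
                m0, sd = model.prior_for(name)
                logp += float(
                    np.sum(-0.5 * ((v - m0) / sd) ** 2 - np.log(sd) - 0.5 * _LOG2PI)
                )
                grad[sl] += -(v - m0) / sd**2
        return logp, grad

    def value(self, x: np.ndarray) -> float:
        return self.value_and_grad(x)[0]

    def initial_vector(self) -> np.ndarray:
        return self.template.vector.copy()


def log_posterior(
    state: Union[ModelState, np.ndarray],
    data: list,
    model: MovementModel,
) -> float:
    """Joint unnormalized log posterior of the hierarchy (whitened coordinates)."""
    post = Posterior(model, data)
    vec = state.vector if isinstance(state, ModelState) else np.asarray(state)
    return post.value(vec)


def log_posterior_and_grad(
    state: Union[ModelState, np.ndarray],
    data: list,
    model: MovementModel,
) -> tuple:
    """Log posterior and its exact gradient with respect to the flat state."""
    post = Posterior(model, data)
    vec = state.vector if isinstance(state, ModelState) else np.asarray(state)
    return post.value_and_grad(vec)
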