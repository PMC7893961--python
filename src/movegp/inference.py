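"""Adaptive MALA sampling, hyperparameter optimization, and MCMC diagnostics.

The sampler is the Metropolis-adjusted Langevin algorithm: proposals drift
along the gradient of the log posterior,

    x' = x + (eps^2 / 2) D grad(x) + eps sqrt(D) xi,   xi ~ N(0, I),

with a Metropolis-Hastings correction that accounts for the asymmetric
proposal.  During burn-in the step size eps is tuned by Robbins-Monro toward
a target acceptance rate (0.574, the MALA optimum) and a diagonal
preconditioner D is estimated from the burn-in draws; both are frozen after
burn-in.  Convergence is monitored with the Gelman-Rubin potential scale
reduction factor and autocorrelation-based effective sample sizes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Callable, Optional

import numpy as np
import scipy.linalg as sla

from .model import MovementModel, Posterior

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerConfig",
    "PosteriorSamples",
    "OptimizerConfig",
    "Preconditioner",
    "mala_step",
    "laplace_preconditioner",
    "run_chains",
    "psrf",
    "effective_sample_size",
    "optimize_hyperparameters",
]

MALA_TARGET_ACCEPTANCE = 0.574


@dataclass
class SamplerConfig:
    """MCMC run settings; ``n_burnin`` steps adapt and are discarded."""

    n_steps: int = 10000
    n_burnin: int = 2500
    thin: int = 1
    n_chains: int = 4
    initial_step_size: float = 0.1
    target_acceptance: float = MALA_TARGET_ACCEPTANCE
    seed: int = 0
    initial_jitter: float = 0.5  # sd of the random spread of chain starts

    def __post_init__(self) -> None:
        if not (0 <= self.n_burnin < self.n_steps):
            raise ValueError("need 0 <= n_burnin < n_steps")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin >= 1 and n_chains >= 1 required")
        if not (0 < self.target_acceptance < 1):
            raise ValueError("target_acceptance must lie in (0, 1)")
        if self.initial_step_size <= 0:
            raise ValueError("initial_step_size must be positive")


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws: array of shape (chain, draw, parameter)."""

    draws: np.ndarray
    names: list
    index: dict
    acceptance: np.ndarray
    step_sizes: np.ndarray
    config: SamplerConfig
    seed: int

    def get(self, name: str) -> np.ndarray:
        """Draws for one named block, shape (chain, draw, size)."""
        return self.draws[:, :, self.index[name]]

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def flat_names(self) -> list:
        out = []
        for name, sl in self.index.items():
            k = sl.stop - sl.start
            out.extend([name] if k == 1 else [f"{name}[{i}]" for i in range(k)])
        return out

    def save(self, path: str) -> None:
        """Persist to a self-describing .npz (draws, names, config, seeds)."""
        meta = {
            "names": list(self.index.keys()),
            "slices": {k: [v.start, v.stop] for k, v in self.index.items()},
            "config": asdict(self.config),
            "seed": self.seed,
        }
        np.savez(
            path,
            draws=self.draws,
            acceptance=self.acceptance,
            step_sizes=self.step_sizes,
            meta=json.dumps(meta),
        )

    @classmethod
    def load(cls, path: str) -> "PosteriorSamples":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            index = {k: slice(a, b) for k, (a, b) in meta["slices"].items()}
            return cls(
                draws=z["draws"],
                names=meta["names"],
                index=index,
                acceptance=z["acceptance"],
                step_sizes=z["step_sizes"],
                config=SamplerConfig(**meta["config"]),
                seed=meta["seed"],
            )


# ----------------------------------------------------------------------
# MALA
# ----------------------------------------------------------------------


class Preconditioner:
    """Proposal metric for MALA: identity, diagonal, or dense covariance.

    Dense metrics are shrunk toward their diagonal and factorized once;
    ``apply`` computes D @ v, ``noise`` draws N(0, D), and ``quad`` the
    quadratic form v' D^{-1} v needed by the Hastings correction.
    """

    def __init__(self, matrix: Optional[np.ndarray] = None, dim: int = 0):
        if matrix is None:
            self.diag = np.ones(dim)
            self.dense = None
        elif matrix.ndim == 1:
            self.diag = matrix
            self.dense = None
        else:
            self.dense = matrix
            self.chol = np.linalg.cholesky(matrix)
            self.diag = None

    @classmethod
    def from_draws(cls, draws: np.ndarray) -> "Preconditioner":
        """Estimate from burn-in draws: dense if there are enough of them
        (rows > 2 x dim), else diagonal; always floored/regularized."""
        n, d = draws.shape
        var = np.var(draws, axis=0)
        floor = 1e-8 * float(np.max(var)) + 1e-12
        if n <= 2 * d:
            return cls(np.maximum(var, floor))
        cov = np.cov(draws.T)
        # shrink toward the diagonal for a stable factorization
        cov = 0.9 * cov + 0.1 * np.diag(np.maximum(var, floor))
        cov[np.diag_indices_from(cov)] += floor
        try:
            return cls(cov)
        except np.linalg.LinAlgError:
            return cls(np.maximum(var, floor))

    def apply(self, v: np.ndarray) -> np.ndarray:
        if self.dense is not None:
            return self.dense @ v
        return self.diag * v

    def noise(self, rng: np.random.Generator, n: int) -> np.ndarray:
        xi = rng.standard_normal(n)
        if self.dense is not None:
            return self.chol @ xi
        return np.sqrt(self.diag) * xi

    def quad(self, v: np.ndarray) -> float:
        if self.dense is not None:
            y = sla.solve_triangular(self.chol, v, lower=True, check_finite=False)
            return float(y @ y)
        return float(np.sum(v**2 / self.diag))


def _as_precond(precond, dim: int) -> Preconditioner:
    if precond is None:
        return Preconditioner(dim=dim)
    if isinstance(precond, Preconditioner):
        return precond
    return Preconditioner(np.asarray(precond, dtype=float))


def _mala_step_cached(
    x: np.ndarray,
    logp: float,
    grad: np.ndarray,
    logpost_and_grad: Callable,
    step_size: float,
    rng: np.random.Generator,
    precond=None,
):
    """One MALA transition reusing the cached (logp, grad) at ``x``.

    Returns (x_new, logp_new, grad_new, accepted, accept_prob).
    """
    if not np.all(np.isfinite(grad)):
        raise FloatingPointError(
            f"non-finite gradient in MALA proposal; state={x!r}"
        )
    P = _as_precond(precond, len(x))
    e2 = step_size**2
    mean_fwd = x + 0.5 * e2 * P.apply(grad)
    prop = mean_fwd + step_size * P.noise(rng, len(x))
    logp_p, grad_p = logpost_and_grad(prop)
    if not np.isfinite(logp_p):
        return x, logp, grad, False, 0.0
    mean_rev = prop + 0.5 * e2 * P.apply(grad_p)
    log_q_fwd = -0.5 * P.quad(prop - mean_fwd) / e2
    log_q_rev = -0.5 * P.quad(x - mean_rev) / e2
    log_ratio = (logp_p - logp) + (log_q_rev - log_q_fwd)
    accept_prob = float(min(1.0, np.exp(min(0.0, log_ratio))))
    if np.log(rng.uniform()) < log_ratio:
        return prop, logp_p, grad_p, True, accept_prob
    return x, logp, grad, False, accept_prob


def laplace_preconditioner(
    logpost_and_grad: Callable,
    x0: np.ndarray,
    eps: float = 1e-4,
    floor_abs: float = 0.1,
) -> Preconditioner:
    """Dense proposal metric from a Laplace approximation at ``x0``.

    The Hessian of the negative log posterior is formed by central finite
    differences of the exact gradient and symmetrized; its eigenvalues are
    floored at ``floor_abs`` — flat or slightly negative directions at an
    imperfect MAP would otherwise blow up the metric, and with standard
    normal whitened priors and sd-2 scalar priors the true posterior
    curvature cannot fall much below this anyway.  The metric is the
    floored inverse — the posterior covariance under the Gaussian
    approximation."""
    x0 = np.asarray(x0, dtype=float)
    d = len(x0)
    H = np.empty((d, d))
    for j in range(d):
        xp, xm = x0.copy(), x0.copy()
        xp[j] += eps
        xm[j] -= eps
        H[:, j] = (logpost_and_grad(xp)[1] - logpost_and_grad(xm)[1]) / (2 * eps)
    H = -0.5 * (H + H.T)
    evals, vecs = np.linalg.eigh(H)
    evals = np.maximum(evals, floor_abs)
    cov = (vecs / evals) @ vecs.T
    return Preconditioner(0.5 * (cov + cov.T))


def mala_step(
    state: np.ndarray,
    logpost_value_and_gradient: Callable,
    step_size: float,
    rng: np.random.Generator,
    precond: Optional[np.ndarray] = None,
):
    """One Metropolis-adjusted Langevin step; returns ``(new_state, accepted)``."""
    logp, grad = logpost_value_and_gradient(np.asarray(state, dtype=float))
    x_new, _, _, accepted, _ = _mala_step_cached(
        np.asarray(state, dtype=float),
        logp,
        grad,
        logpost_value_and_gradient,
        step_size,
        rng,
        precond,
    )
    return x_new, accepted


def _run_single_chain(
    logpost_and_grad: Callable,
    x0: np.ndarray,
    config: SamplerConfig,
    rng: np.random.Generator,
    precond: Optional[Preconditioner] = None,
):
    dim = len(x0)
    B = config.n_burnin
    n_keep = (config.n_steps - B) // config.thin
    kept = np.empty((n_keep, dim))
    x = x0.copy()
    logp, grad = logpost_and_grad(x)
    step = config.initial_step_size
    fixed_metric = precond is not None
    if precond is None:
        precond = Preconditioner(dim=dim)
    burn_draws = np.empty((max(B, 1), dim))
    # windowed adaptation (no externally supplied metric): the preconditioner
    # is re-estimated from the most recent burn-in window at each refresh
    # point, and the Robbins-Monro step-size schedule restarts so the step
    # can re-tune to the new metric quickly.  A supplied metric is kept
    # fixed — covariance estimates from short autocorrelated windows are
    # strictly worse.
    refreshes = (
        [int(B * f) for f in (0.25, 0.5, 0.75)] if (B >= 40 and not fixed_metric) else []
    )
    phase_start = 0
    n_acc_post = 0
    n_post = 0
    recent: list = []
    ki = 0
    aprob_hist: list = []
    for t in range(config.n_steps):
        x, logp, grad, accepted, aprob = _mala_step_cached(
            x, logp, grad, logpost_and_grad, step, rng, precond
        )
        if t < B:
            aprob_hist.append(aprob)
            k = t - phase_start + 1
            step = float(
                np.exp(np.log(step) + (aprob - config.target_acceptance) / k**0.6)
            )
            burn_draws[t] = x
            if t in refreshes:
                prev = refreshes[refreshes.index(t) - 1] if refreshes.index(t) else 0
                precond = Preconditioner.from_draws(burn_draws[prev:t])
                phase_start = t
            elif t - phase_start >= 200 and t % 50 == 0:
                # rescue: if acceptance has collapsed late in burn-in when
                # the Robbins-Monro gain is already small, restart the
                # schedule so the step size can re-tune quickly
                if np.mean(aprob_hist[-200:]) < 0.1:
                    phase_start = t
        else:
            n_post += 1
            n_acc_post += int(accepted)
            if (t - B) % config.thin == 0 and ki < n_keep:
                kept[ki] = x
                ki += 1
        recent.append(int(accepted))
        if len(recent) >= 200:
            if sum(recent) / len(recent) < 0.01:
                logger.warning(
                    "MALA acceptance below 1%% over the last %d steps", len(recent)
                )
            recent = []
    acc_rate = n_acc_post / max(n_post, 1)
    return kept[:ki], acc_rate, step


def run_chains(
    model: MovementModel,
    data: list,
    config: SamplerConfig,
    posterior: Optional[Posterior] = None,
    start: Optional[np.ndarray] = None,
    precond: Optional[Preconditioner] = None,
) -> PosteriorSamples:
    """Run independent adaptive-MALA chains on the model posterior.

    Each chain gets its own sub-seed (spawned from ``config.seed``) and an
    overdispersed start around ``start`` (the model's current state by
    default; pass a MAP-optimized vector for the optimize-then-sample
    workflow).  A fixed proposal metric (e.g. from
    :func:`laplace_preconditioner`) is used as-is with only step-size
    adaptation; otherwise the metric is estimated from burn-in windows.
    Adaptation happens only during burn-in, and post-burn-in draws are
    thinned by ``thin``.  Identical configs give bit-identical results.
    """
    post = posterior if posterior is not None else Posterior(model, data)
    x0 = post.initial_vector() if start is None else np.asarray(start, dtype=float)
    children = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = []
    accs = []
    steps = []
    for c, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        x_start = x0 + config.initial_jitter * rng.standard_normal(len(x0))
        kept, acc, step = _run_single_chain(
            post.value_and_grad, x_start, config, rng, precond=precond
        )
        chains.append(kept)
        accs.append(acc)
        steps.append(step)
        logger.info("chain %d: acceptance %.3f, final step %.2e", c, acc, step)
    draws = np.stack(chains)
    return PosteriorSamples(
        draws=draws,
        names=list(post.template.index.keys()),
        index=dict(post.template.index),
        acceptance=np.array(accs),
        step_sizes=np.array(steps),
        config=config,
        seed=config.seed,
    )


# ----------------------------------------------------------------------
# Diagnostics
# ----------------------------------------------------------------------


def _as_draws_array(samples) -> np.ndarray:
    if isinstance(samples, PosteriorSamples):
        return samples.draws
    a = np.asarray(samples, dtype=float)
    if a.ndim == 2:
        a = a[:, :, None]
    if a.ndim != 3:
        raise ValueError("expected draws of shape (chain, draw[, parameter])")
    return a


@dataclass
class DiagnosticResult:
    per_parameter: np.ndarray
    max: float
    names: Optional[list] = None

    def table(self) -> str:
        names = self.names or [f"p{i}" for i in range(len(self.per_parameter))]
        lines = [f"{n}\t{v:.4f}" for n, v in zip(names, self.per_parameter)]
        return "\n".join(lines)


def psrf(samples) -> DiagnosticResult:
    """Gelman-Rubin potential scale reduction factor per parameter.

    With W the mean within-chain variance and B/n the variance of the chain
    means (sample variance over chains, the n/(n-1)-free convention), the
    statistic is sqrt(((n-1)/n * W + B/n) / W); values near 1 indicate the
    chains have mixed.
    """
    a = _as_draws_array(samples)
    m, n, d = a.shape
    if m < 2 or n < 10:
        raise ValueError("psrf needs at least 2 chains of 10 draws")
    W = np.mean(np.var(a, axis=1, ddof=1), axis=0)
    if np.any(W == 0):
        raise ValueError("degenerate chain: zero within-chain variance")
    B_over_n = np.var(np.mean(a, axis=1), axis=0, ddof=1)
    r = np.sqrt(((n - 1) / n * W + B_over_n) / W)
    names = samples.flat_names() if isinstance(samples, PosteriorSamples) else None
    return DiagnosticResult(per_parameter=r, max=float(np.max(r)), names=names)


def _chain_autocov(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance of one chain via FFT."""
    n = len(x)
    xd = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xd, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    return acov


def effective_sample_size(samples) -> DiagnosticResult:
    """Autocorrelation-based ESS with Geyer's initial positive sequence.

    Pooled over chains: rho_t = 1 - (W - mean autocovariance_t) / var+, with
    paired sums truncated at the first non-positive pair; ESS = m*n / tau,
    capped at the total number of draws.
    """
    a = _as_draws_array(samples)
    m, n, d = a.shape
    if n < 10:
        raise ValueError("effective_sample_size needs at least 10 draws")
    out = np.empty(d)
    for j in range(d):
        acovs = np.stack([_chain_autocov(a[c, :, j]) for c in range(m)])
        mean_acov = acovs.mean(axis=0)
        W = np.mean([np.var(a[c, :, j], ddof=1) for c in range(m)])
        if W == 0:
            raise ValueError("degenerate chain: zero within-chain variance")
        if m > 1:
            B_over_n = np.var(a[:, :, j].mean(axis=1), ddof=1)
        else:
            B_over_n = 0.0
        var_plus = W * (n - 1) / n + B_over_n
        rho = 1.0 - (W - mean_acov) / var_plus
        # Geyer initial positive sequence on paired sums
        s = 0.0
        t = 1
        while t + 1 < n:
            pair = rho[t] + rho[t + 1]
            if pair <= 0:
                break
            s += pair
            t += 2
        tau = 1.0 + 2.0 * s
        out[j] = min(m * n, m * n / max(tau, 1.0 / (m * n)))
    names = samples.flat_names() if isinstance(samples, PosteriorSamples) else None
    return DiagnosticResult(per_parameter=out, max=float(np.max(out)), names=names)


# ----------------------------------------------------------------------
# Hyperparameter optimization
# ----------------------------------------------------------------------


@dataclass
class OptimizerConfig:
    """First-order (Adam) optimizer settings for MAP/hyperparameter fitting."""

    learning_rate: float = 0.05
    n_iters: int = 500
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    only: Optional[list] = None  # restrict updates to these state names


def optimize_hyperparameters(
    model: MovementModel,
    data_subset: list,
    config: OptimizerConfig = OptimizerConfig(),
) -> tuple:
    """Minimize the negative log posterior with Adam.

    By default all state coordinates (latents and hyperparameters) are
    optimized jointly — a MAP fit whose hyperparameter entries can then be
    frozen before sampling.  ``config.only`` restricts the update to a subset
    of named blocks.  Returns ``(theta_hat, loss_trace, state)`` where
    ``theta_hat`` maps each scalar state entry to its optimized value.
    """
    if not data_subset:
        raise ValueError("data_subset must be nonempty")
    post = Posterior(model, data_subset)
    x = post.initial_vector()
    mask = np.ones_like(x)
    if config.only is not None:
        mask[:] = 0.0
        for name in config.only:
            mask[post.template.index[name]] = 1.0
    mom = np.zeros_like(x)
    vel = np.zeros_like(x)
    trace = []
    for t in range(1, config.n_iters + 1):
        logp, grad = post.value_and_grad(x)
        loss = -logp
        if not np.isfinite(loss):
            raise FloatingPointError(
                "optimization diverged (loss is not finite); try a smaller learning rate"
            )
        trace.append(loss)
        g = -grad * mask
        mom = config.beta1 * mom + (1 - config.beta1) * g
        vel = config.beta2 * vel + (1 - config.beta2) * g**2
        mhat = mom / (1 - config.beta1**t)
        vhat = vel / (1 - config.beta2**t)
        x = x - config.learning_rate * mhat / (np.sqrt(vhat) + config.eps)
    state = post.template.with_vector(x)
    theta_hat = {
        name: (float(v[0]) if v.size == 1 else v.copy())
        for name, v in state.to_dict().items()
    }
    return theta_hat, np.array(trace), state
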