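"""Covariance functions for movement-process and latent-parameter GPs.

The movement process itself is an Ornstein-Uhlenbeck (OU) walk, whose GP
counterpart is the Matérn 1/2 (exponential) kernel.  Behavioural
non-stationarity enters through a generalisation of that kernel in which
the amplitude sigma(t) and correlation lengthscale L(t) are functions of
time.  The latent functions sigma(t), L(t) and the mean location m(t) get
their own lower-level kernels: periodic (daily rhythms), quasi-periodic
(an annual cycle modulated by a slow squared-exponential trend), or plain
Matérn 1/2.

All builders return dense covariance matrices; amplitude parameters are
zero-lag variances throughout (the stationary kernel's ``sigma_k`` equals
the non-stationary kernel's diagonal ``sigma(t)**2`` under constant
parameters, so the two forms agree entrywise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky

__all__ = [
    "StationaryMatern12Params",
    "PeriodicKernelParams",
    "QuasiPeriodicKernelParams",
    "NonStationaryInputs",
    "OUParams",
    "matern12_cov",
    "nonstationary_matern12_cov",
    "periodic_cov",
    "quasiperiodic_cov",
    "ou_to_kernel",
    "kernel_to_ou",
    "add_jitter",
]


def _check_times(t: np.ndarray, name: str) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError(f"{name} contains non-finite values")
    return t


def _abs_diff(times_a: np.ndarray, times_b: np.ndarray) -> np.ndarray:
    return np.abs(times_a[:, None] - times_b[None, :])


@dataclass(frozen=True)
class StationaryMatern12Params:
    """Exponential-kernel parameters: zero-lag variance and lengthscale.

    ``sigma_k`` is the variance at zero lag (squared position or velocity
    units); ``L`` is the correlation lengthscale in time units.
    """

    sigma_k: float
    L: float

    def __post_init__(self) -> None:
        if not (self.sigma_k > 0 and self.L > 0):
            raise ValueError("sigma_k and L must be strictly positive")

    # --- hooks used by the latent-GP machinery -------------------------
    # make_features precomputes whatever depends only on the (fixed) time
    # differences, so repeated evaluations at new hyperparameters avoid
    # transcendental recomputation.
    def make_features(self, D: np.ndarray) -> np.ndarray:
        return D

    def cov_from_features(self, D: np.ndarray) -> np.ndarray:
        return self.sigma_k * np.exp(-D / self.L)

    def cov_from_absdiff(self, D: np.ndarray) -> np.ndarray:
        return self.cov_from_features(self.make_features(D))

    def cov_grad_log_features(self, name: str, D: np.ndarray, K: np.ndarray) -> np.ndarray:
        if name == "sigma_k":
            return K
        if name == "L":
            return K * (D / self.L)
        raise KeyError(name)

    def cov_grad_log(self, name: str, D: np.ndarray, K: np.ndarray) -> np.ndarray:
        """dK/d(log param) for ``name`` in {'sigma_k', 'L'}."""
        return self.cov_grad_log_features(name, self.make_features(D), K)

    def replace_log(self, **log_updates: float) -> "StationaryMatern12Params":
        kw = {"sigma_k": self.sigma_k, "L": self.L}
        for k, v in log_updates.items():
            kw[k] = float(np.exp(v))
        return StationaryMatern12Params(**kw)

    def log_value(self, name: str) -> float:
        return float(np.log(getattr(self, name)))


@dataclass(frozen=True)
class PeriodicKernelParams:
    """Exactly periodic kernel ``a * exp(-2 sin^2(pi |dt| / P) / l^2)``.

    ``P`` is the period (24 h for diurnal rhythms, 1 yr for seasonal), ``a``
    the latent-function variance and ``l`` a dimensionless wiggliness scale.
    """

    a: float
    l: float
    P: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.l > 0 and self.P > 0):
            raise ValueError("a, l, P must be strictly positive")

    def make_features(self, D: np.ndarray) -> np.ndarray:
        return np.sin(np.pi * D / self.P) ** 2

    def cov_from_features(self, s2: np.ndarray) -> np.ndarray:
        return self.a * np.exp(-2.0 * s2 / self.l**2)

    def cov_from_absdiff(self, D: np.ndarray) -> np.ndarray:
        return self.cov_from_features(self.make_features(D))

    def cov_grad_log_features(self, name: str, s2: np.ndarray, K: np.ndarray) -> np.ndarray:
        if name == "a":
            return K
        if name == "l":
            return K * (4.0 * s2 / self.l**2)
        raise KeyError(name)

    def cov_grad_log(self, name: str, D: np.ndarray, K: np.ndarray) -> np.ndarray:
        return self.cov_grad_log_features(name, self.make_features(D), K)

    def replace_log(self, **log_updates: float) -> "PeriodicKernelParams":
        kw = {"a": self.a, "l": self.l, "P": self.P}
        for k, v in log_updates.items():
            kw[k] = float(np.exp(v))
        return PeriodicKernelParams(**kw)

    def log_value(self, name: str) -> float:
        return float(np.log(getattr(self, name)))


@dataclass(frozen=True)
class QuasiPeriodicKernelParams:
    """Periodic kernel times a squared-exponential envelope.

    The product ``a * exp(-dt^2/(2 lam^2)) * exp(-2 sin^2(pi|dt|/P)/l^2)``
    encodes a cycle of period ``P`` whose shape drifts on timescale ``lam``
    (e.g. an annual migration with a range shifting over several years).
    """

    a: float
    lam: float
    l: float
    P: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.lam > 0 and self.l > 0 and self.P > 0):
            raise ValueError("all quasi-periodic parameters must be positive")

    def make_features(self, D: np.ndarray) -> tuple:
        return (D**2, np.sin(np.pi * D / self.P) ** 2)

    def cov_from_features(self, feat: tuple) -> np.ndarray:
        d2, s2 = feat
        return self.a * np.exp(-d2 / (2.0 * self.lam**2) - 2.0 * s2 / self.l**2)

    def cov_from_absdiff(self, D: np.ndarray) -> np.ndarray:
        return self.cov_from_features(self.make_features(D))

    def cov_grad_log_features(self, name: str, feat: tuple, K: np.ndarray) -> np.ndarray:
        d2, s2 = feat
        if name == "a":
            return K
        if name == "l":
            return K * (4.0 * s2 / self.l**2)
        if name == "lam":
            return K * (d2 / self.lam**2)
        raise KeyError(name)

    def cov_grad_log(self, name: str, D: np.ndarray, K: np.ndarray) -> np.ndarray:
        return self.cov_grad_log_features(name, self.make_features(D), K)

    def replace_log(self, **log_updates: float) -> "QuasiPeriodicKernelParams":
        kw = {"a": self.a, "lam": self.lam, "l": self.l, "P": self.P}
        for k, v in log_updates.items():
            kw[k] = float(np.exp(v))
        return QuasiPeriodicKernelParams(**kw)

    def log_value(self, name: str) -> float:
        return float(np.log(getattr(self, name)))


@dataclass(frozen=True)
class NonStationaryInputs:
    """Evaluation times with pointwise amplitude and lengthscale values."""

    times: np.ndarray
    sigma_of_t: np.ndarray
    L_of_t: np.ndarray

    def __post_init__(self) -> None:
        t = _check_times(self.times, "times")
        s = np.asarray(self.sigma_of_t, dtype=float)
        L = np.asarray(self.L_of_t, dtype=float)
        if not (len(t) == len(s) == len(L)):
            raise ValueError("times, sigma_of_t, L_of_t must have equal length")
        if not (np.all(s > 0) and np.all(L > 0)):
            raise ValueError("sigma_of_t and L_of_t must be strictly positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "sigma_of_t", s)
        object.__setattr__(self, "L_of_t", L)


@dataclass(frozen=True)
class OUParams:
    """Ornstein-Uhlenbeck SDE parameters.

    ``nu``: mean-reversion rate (1/time); ``eta``: noise amplitude of the
    Wiener term; ``m``: the 2-D mean location (unused by the kernel map).
    """

    nu: float
    eta: float
    m: tuple[float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.nu > 0:
            raise ValueError("nu must be strictly positive")
        if self.eta < 0:
            raise ValueError("eta must be non-negative")


def matern12_cov(
    times_a: np.ndarray, times_b: np.ndarray, params: StationaryMatern12Params
) -> np.ndarray:
    """Exponential covariance ``sigma_k * exp(-|t - t'| / L)``."""
    ta = _check_times(times_a, "times_a")
    tb = _check_times(times_b, "times_b")
    return params.cov_from_absdiff(_abs_diff(ta, tb))


def nonstationary_matern12_cov(
    inputs_a: NonStationaryInputs, inputs_b: NonStationaryInputs
) -> np.ndarray:
    """Matérn 1/2 covariance with time-varying amplitude and lengthscale.

    Entries are::

        sqrt(2 s(t)^2 s(t')^2 L(t) L(t') / (L(t)^2 + L(t')^2))
            * exp(-sqrt(2 (t-t')^2 / (L(t)^2 + L(t')^2)))

    The diagonal on matched inputs is ``sigma(t)**2``, and constant
    ``sigma``/``L`` recover :func:`matern12_cov` with
    ``sigma_k = sigma**2`` exactly.
    """
    La, Lb = inputs_a.L_of_t, inputs_b.L_of_t
    sa, sb = inputs_a.sigma_of_t, inputs_b.sigma_of_t
    S = La[:, None] ** 2 + Lb[None, :] ** 2
    pref = np.sqrt(
        2.0 * (sa[:, None] ** 2) * (sb[None, :] ** 2) * La[:, None] * Lb[None, :] / S
    )
    dt = inputs_a.times[:, None] - inputs_b.times[None, :]
    return pref * np.exp(-np.sqrt(2.0 * dt**2 / S))


def periodic_cov(
    times_a: np.ndarray, times_b: np.ndarray, params: PeriodicKernelParams
) -> np.ndarray:
    """Exactly periodic covariance; invariant under shifts by the period."""
    ta = _check_times(times_a, "times_a")
    tb = _check_times(times_b, "times_b")
    return params.cov_from_absdiff(_abs_diff(ta, tb))


def quasiperiodic_cov(
    times_a: np.ndarray, times_b: np.ndarray, params: QuasiPeriodicKernelParams
) -> np.ndarray:
    """Periodic times squared-exponential covariance (slowly drifting cycle)."""
    ta = _check_times(times_a, "times_a")
    tb = _check_times(times_b, "times_b")
    return params.cov_from_absdiff(_abs_diff(ta, tb))


def ou_to_kernel(params: OUParams) -> StationaryMatern12Params:
    """Map OU SDE parameters to the exponential kernel: L = 1/nu, sigma_k = eta^2/(2 nu)."""
    return StationaryMatern12Params(
        sigma_k=params.eta**2 / (2.0 * params.nu), L=1.0 / params.nu
    )


def kernel_to_ou(params: StationaryMatern12Params) -> OUParams:
    """Inverse of :func:`ou_to_kernel`; the mean location is left unset."""
    nu = 1.0 / params.L
    eta = float(np.sqrt(2.0 * nu * params.sigma_k))
    return OUParams(nu=nu, eta=eta, m=None)


def add_jitter(
    matrix: np.ndarray,
    jitter: float | None = None,
    max_retries: int = 3,
) -> np.ndarray:
    """Return ``matrix + jitter * I`` such that a Cholesky factorization succeeds.

    ``jitter`` defaults to ``1e-6`` times the mean diagonal (or 1e-6 for an
    all-zero diagonal) and is doubled on each failed attempt, up to
    ``max_retries`` retries.
    """
    K = np.asarray(matrix, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("add_jitter requires a square matrix")
    if jitter is None:
        scale = float(np.mean(np.diag(K)))
        jitter = 1e-6 * scale if scale > 0 else 1e-6
    eye = np.eye(K.shape[0])
    for _ in range(max_retries + 1):
        out = K + jitter * eye
        try:
            cholesky(out, lower=True)
            return out
        except np.linalg.LinAlgError:
            jitter *= 2.0
    raise np.linalg.LinAlgError(
        f"matrix not positive definite after {max_retries} jitter retries"
    )
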