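"""The OU <-> kernel correspondence and the non-stationary Matérn 1/2.

Builds the exponential covariance implied by an Ornstein-Uhlenbeck walker,
shows that freezing the non-stationary kernel's parameters recovers it, and
prints covariances at a few lags.
"""

import numpy as np

from movegp import (
    NonStationaryInputs,
    OUParams,
    matern12_cov,
    nonstationary_matern12_cov,
    ou_to_kernel,
)

ou = OUParams(nu=2.0, eta=1.0)
kern = ou_to_kernel(ou)
print(f"OU walker nu={ou.nu}, eta={ou.eta}")
print(f"-> exponential kernel: zero-lag variance sigma_k={kern.sigma_k:.3f}, "
      f"lengthscale L={kern.L:.3f}")
# sigma_k = eta^2/(2 nu) is the walker's stationary variance; L = 1/nu is
# its decorrelation time.

lags = np.array([0.0, 0.25, 0.5, 1.0, 2.0])
cov = matern12_cov(np.zeros(1), lags, kern)[0]
for lag, c in zip(lags, cov):
    print(f"  cov at lag {lag:4.2f} = {c:.4f}")

# the non-stationary kernel with constant sigma(t), L(t) is the same matrix
t = np.linspace(0, 2, 5)
const = NonStationaryInputs(t, np.full(5, np.sqrt(kern.sigma_k)), np.full(5, kern.L))
diff = np.max(np.abs(
    nonstationary_matern12_cov(const, const) - matern12_cov(t, t, kern)
))
print(f"max |non-stationary(const) - stationary| = {diff:.2e}  (machine precision)")
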