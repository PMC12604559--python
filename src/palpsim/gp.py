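"""Exact Gaussian-process regression over the palpation grid.

The stiffness field is modelled as a zero-mean GP with a squared-exponential
kernel k(x, x') = sigma_k^2 * exp(-||x - x'||^2 / (2 l^2)).  Given the
palpation dataset D_t = {(x_i, f(x_i))}, the posterior mean and variance at
the query points follow the standard conjugate formulas

    mu(q)     = k(q, X) (K + sigma_n^2 I)^-1 f(X)
    sigma2(q) = k(q, q) - k(q, X) (K + sigma_n^2 I)^-1 k(X, q)

evaluated through a Cholesky factorization of the regularized Gram matrix.
Hyperparameters are fixed per run (no marginal-likelihood optimization):
on the normalized observation scale the defaults are sigma_k^2 = 1,
l = 0.5 mm and sigma_n^2 = 1e-4.  The length scale sets the resolution of
the recovered inclusion boundary: at 0.5 mm (2.5 fine-grid cells, a quarter
of the circular inclusion's radius) the thresholded posterior can localize
the boundary to about a grid cell, whereas smoothing at the inclusion's own
scale blurs the 0.5 level set by a millimetre regardless of how many probes
are spent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

JITTER = 1e-8


@dataclass(frozen=True)
class GPConfig:
    kernel_variance: float = 1.0  # sigma_k^2, signal variance
    length_scale: float = 0.5  # l, mm
    noise_variance: float = 1e-4  # sigma_n^2

    def __post_init__(self) -> None:
        if self.kernel_variance <= 0 or self.length_scale <= 0:
            raise ValueError("kernel variance and length scale must be positive")
        if self.noise_variance < 0:
            raise ValueError("noise variance must be non-negative")

    def key(self) -> tuple:
        return (self.kernel_variance, self.length_scale, self.noise_variance)


@dataclass
class ObservationSet:
    """Palpation dataset: probed locations (mm) and observed values."""

    X: np.ndarray  # (t, 2)
    y: np.ndarray  # (t,)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("locations and values must have the same count")

    def __len__(self) -> int:
        return len(self.y)

    @classmethod
    def empty(cls) -> "ObservationSet":
        return cls(X=np.empty((0, 2)), y=np.empty((0,)))

    def appended(self, x: np.ndarray, value: float) -> "ObservationSet":
        return ObservationSet(X=np.vstack([self.X, np.atleast_2d(x)]),
                              y=np.append(self.y, value))


@dataclass
class GPPosterior:
    """Posterior mean/variance fields evaluated at fixed query points."""

    query: np.ndarray  # (m, 2)
    mean: np.ndarray  # (m,)
    var: np.ndarray  # (m,) clipped to >= 0


def se_kernel(xa, xb, config: GPConfig) -> np.ndarray:
    """Squared-exponential covariance between two point sets (mm)."""
    xa = np.atleast_2d(np.asarray(xa, dtype=float))
    xb = np.atleast_2d(np.asarray(xb, dtype=float))
    sq = ((xa[:, None, :] - xb[None, :, :]) ** 2).sum(-1)
    return config.kernel_variance * np.exp(-sq / (2.0 * config.length_scale**2))


def _gram_cholesky(X: np.ndarray, config: GPConfig):
    K = se_kernel(X, X, config)
    K[np.diag_indices_from(K)] += config.noise_variance
    try:
        return cho_factor(K, lower=True)
    except np.linalg.LinAlgError:
        warnings.warn("singular Gram matrix: adding diagonal jitter", stacklevel=2)
        K[np.diag_indices_from(K)] += JITTER
        return cho_factor(K, lower=True)


def posterior(obs: ObservationSet, query_points: np.ndarray,
              config: GPConfig) -> GPPosterior:
    """Exact GP posterior at ``query_points``; the prior when ``obs`` is empty."""
    q = np.atleast_2d(np.asarray(query_points, dtype=float))
    if len(obs) == 0:
        return GPPosterior(query=q,
                           mean=np.zeros(len(q)),
                           var=np.full(len(q), config.kernel_variance))
    c, low = _gram_cholesky(obs.X, config)
    k_star = se_kernel(q, obs.X, config)  # (m, t)
    mean = k_star @ cho_solve((c, low), obs.y)
    # var = k(q,q) - sum of squared half-solves
    v = solve_triangular(c, k_star.T, lower=low)  # (t, m)
    var = config.kernel_variance - (v**2).sum(axis=0)
    return GPPosterior(query=q, mean=mean, var=np.clip(var, 0.0, None))
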