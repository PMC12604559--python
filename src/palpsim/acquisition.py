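"""Acquisition strategies for active palpation.

Six criteria choose the next probing location on the fine grid from the
current GP posterior.  The strategy family is treated as pluggable; the
exact score of each member follows the standard form from the active
learning / Bayesian optimization literature (the benchmark compares the
family, it does not redefine its members):

- EVR   : expected reduction in total posterior variance if x were probed,
          sum_j cov(x_j, x)^2 / (sigma^2(x) + sigma_n^2).
- EI    : expected improvement over the incumbent best observation,
          E[max(f - f_best - xi, 0)] under N(mu, sigma^2).
- UCB   : optimistic bound mu + beta * sigma.
- LSE   : level-set ambiguity min(mu + beta*sigma - h, h - (mu - beta*sigma)),
          largest where the confidence interval straddles the level h.
- ILS-UCB: gamma * sigma - (1 - gamma) * |mu - h|, trading posterior
          uncertainty against closeness to the implicit level set.
- RASEC : UCB score rescaled to [0, 1] over the unvisited candidates and
          penalized by travel cost lambda_e * ||x - x_t|| from the current
          position (a linear stand-in for the cited rescaling schedule).

Ties are broken by the lowest flat grid index, so traces are deterministic.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.linalg import solve_triangular
from scipy.stats import norm

from .gp import GPConfig, GPPosterior, ObservationSet, _gram_cholesky, se_kernel
from .phantom import GridSpec


class Strategy(str, Enum):
    EVR = "EVR"
    EI = "EI"
    UCB = "UCB"
    LSE = "LSE"
    ILS_UCB = "ILS-UCB"
    RASEC = "RASEC"


ALL_STRATEGIES = tuple(Strategy)


class ExhaustionError(RuntimeError):
    """Every grid point has already been probed."""


@dataclass(frozen=True)
class AcquisitionConfig:
    strategy: Strategy = Strategy.EI
    beta: float = 1.96  # UCB/LSE exploration weight
    xi: float = 0.01  # EI improvement margin
    level: float = 0.5  # LSE / ILS-UCB target level on the posterior scale
    gamma: float = 0.8  # ILS-UCB level-vs-variance mixing
    lambda_e: float = 0.05  # RASEC travel-cost weight, 1/mm
    n_init: int = 5  # initial random probes

    def __post_init__(self) -> None:
        if self.beta < 0 or self.xi < 0 or self.lambda_e < 0:
            raise ValueError("beta, xi and lambda_e must be non-negative")
        if not (0 < self.level < 1):
            raise ValueError("level must lie in (0, 1)")
        if not (0 <= self.gamma <= 1):
            raise ValueError("gamma must lie in [0, 1]")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")


# Cached prior Gram data for the EVR scorer: the candidate set is the same
# fine grid on every iteration, so k(grid, grid) is computed once.
_EVR_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _grid_gram(query: np.ndarray, config: GPConfig):
    key = (hashlib.blake2b(np.ascontiguousarray(query).tobytes(),
                           digest_size=16).hexdigest(), config.key())
    hit = _EVR_CACHE.get(key)
    if hit is None:
        kgg = se_kernel(query, query, config)
        hit = (kgg, (kgg**2).sum(axis=0))
        _EVR_CACHE.clear()  # keep at most one 50 MB block resident
        _EVR_CACHE[key] = hit
    return hit


def evr_scores(post: GPPosterior, obs: ObservationSet,
               gp_config: GPConfig) -> np.ndarray:
    """Total-posterior-variance reduction for probing each candidate.

    Uses the low-rank identity cov = K_gg - B^T B with B = L^-1 k(X, grid),
    so the N^2 x N^2 posterior covariance is never materialized beyond the
    cached prior Gram matrix.
    """
    q = post.query
    kgg, s0 = _grid_gram(q, gp_config)
    denom = post.var + gp_config.noise_variance
    if len(obs) == 0:
        return s0 / denom
    c, low = _gram_cholesky(obs.X, gp_config)
    b = solve_triangular(c, se_kernel(obs.X, q, gp_config), lower=low)  # (t, m)
    w = b @ kgg  # (t, m)
    s1 = (b * w).sum(axis=0)
    g = b @ b.T
    s2 = (b * (g @ b)).sum(axis=0)
    return (s0 - 2.0 * s1 + s2) / denom


def expected_improvement(mean: np.ndarray, sigma: np.ndarray,
                         f_best: float, xi: float) -> np.ndarray:
    """Closed-form EI under N(mean, sigma^2); zero where sigma = 0 and
    mean does not beat the incumbent."""
    delta = mean - f_best - xi
    out = np.maximum(delta, 0.0)
    pos = sigma > 0
    z = delta[pos] / sigma[pos]
    out = out.astype(float)
    out[pos] = delta[pos] * norm.cdf(z) + sigma[pos] * norm.pdf(z)
    return out


def scores(post: GPPosterior, obs: ObservationSet, config: AcquisitionConfig,
           gp_config: GPConfig,
           current: np.ndarray | None = None) -> np.ndarray:
    """Raw per-candidate acquisition scores (before the visited mask)."""
    mu = post.mean
    sigma = np.sqrt(post.var)
    s = config.strategy
    if s == Strategy.EVR:
        return evr_scores(post, obs, gp_config)
    if s == Strategy.EI:
        f_best = float(obs.y.max()) if len(obs) else 0.0
        return expected_improvement(mu, sigma, f_best, config.xi)
    if s == Strategy.UCB:
        return mu + config.beta * sigma
    if s == Strategy.LSE:
        h = config.level
        return np.minimum(mu + config.beta * sigma - h,
                          h - (mu - config.beta * sigma))
    if s == Strategy.ILS_UCB:
        return config.gamma * sigma - (1 - config.gamma) * np.abs(mu - config.level)
    if s == Strategy.RASEC:
        base = mu + config.beta * sigma
        lo, hi = base.min(), base.max()
        scaled = np.zeros_like(base) if hi == lo else (base - lo) / (hi - lo)
        if current is not None:
            dist = np.linalg.norm(post.query - np.asarray(current), axis=1)
            scaled = scaled - config.lambda_e * dist
        return scaled
    raise ValueError(f"unknown strategy {s!r}")


def next_point(post: GPPosterior, obs: ObservationSet,
               config: AcquisitionConfig, gp_config: GPConfig,
               visited: np.ndarray | None = None,
               current: np.ndarray | None = None) -> tuple[int, np.ndarray]:
    """Select the unvisited candidate maximizing the strategy score.

    Returns ``(flat_index, point)``.  ``visited`` is a boolean mask or index
    array over the posterior's query points; ties break toward the lowest
    flat index.
    """
    sc = scores(post, obs, config, gp_config, current=current)
    if not np.all(np.isfinite(sc)):
        raise FloatingPointError("non-finite acquisition score")
    mask = np.zeros(len(sc), dtype=bool)
    if visited is not None:
        mask[np.asarray(visited)] = True
    if mask.all():
        raise ExhaustionError("all grid points have been probed")
    sc = np.where(mask, -np.inf, sc)
    idx = int(np.argmax(sc))
    return idx, post.query[idx]


def initial_design(grid: GridSpec, n_init: int,
                   rng: np.random.Generator | int | None) -> tuple[np.ndarray, np.ndarray]:
    """``n_init`` distinct uniform-random grid points; reproducible by seed.

    Returns ``(flat_indices, points)``.
    """
    n = grid.n_points
    if n_init > n:
        raise ValueError("n_init exceeds the number of grid points")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    idx = np.sort(gen.choice(n, size=n_init, replace=False))
    return idx, grid.points()[idx]
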