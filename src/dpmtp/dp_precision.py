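"""Posterior inference for the Dirichlet-process precision parameter M.

Given that m draws from a DP(M * nu0) produced k distinct values, and a
Gamma(a, b) prior on M (the Exponential(1) default is a = b = 1), the
posterior density is, up to proportionality,

    pi(M | k)  ∝  pi(M) * M^(k-1) * (M + m) * B(M + 1, m),

where B is the Beta function — the closed form of the integral
``int_0^1 z^M (1 - z)^(m-1) dz``.  Two routes to this posterior are
provided: the Escobar-West auxiliary-variable Gibbs sampler (the
workhorse) and direct quadrature of the density on a grid (an
independent check and a tool for moment computation at small m).

The Gibbs sweep alternates
    eta | M  ~  Beta(M + 1, m)
    M | eta  ~  pi_eta * Gamma(a + k, b - log eta)
               + (1 - pi_eta) * Gamma(a + k - 1, b - log eta),
with mixture odds ``pi_eta / (1 - pi_eta) = (a + k - 1) / (m (b - log eta))``.
Since eta in (0, 1), the rate ``b - log eta`` always exceeds b > 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.special import betaln

__all__ = [
    "PrecisionPosteriorSamples",
    "sample_m_posterior",
    "m_posterior_density_grid",
    "m_posterior_grid_moments",
    "mcse_mean",
]

_QUANTILES = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class PrecisionPosteriorSamples:
    """Retained Gibbs draws of M with run metadata and summaries."""

    draws: np.ndarray
    n_burn: int
    n_keep: int
    prior_shape: float
    prior_rate: float
    k: int
    m: int
    seed: Union[int, None]

    @property
    def mean(self) -> float:
        return float(self.draws.mean())

    @property
    def sd(self) -> float:
        return float(self.draws.std(ddof=1))

    @property
    def median(self) -> float:
        return float(np.median(self.draws))

    @property
    def quantiles(self) -> dict[float, float]:
        qs = np.quantile(self.draws, _QUANTILES)
        return {q: float(v) for q, v in zip(_QUANTILES, qs)}

    @property
    def mcse(self) -> float:
        """Batch-means Monte-Carlo standard error of the posterior mean."""
        return mcse_mean(self.draws)

    def summary(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "mcse_mean": self.mcse,
            "quantiles": {f"{int(q * 100)}%": v
                          for q, v in self.quantiles.items()},
            "k": self.k,
            "m": self.m,
            "n_burn": self.n_burn,
            "n_keep": self.n_keep,
            "prior_shape": self.prior_shape,
            "prior_rate": self.prior_rate,
            "seed": self.seed,
        }


def mcse_mean(draws: np.ndarray, n_batches: int = 50) -> float:
    """Monte-Carlo standard error of the chain mean via batch means.

    Accounts for autocorrelation; n_batches of equal length (trailing
    remainder dropped).
    """
    draws = np.asarray(draws, dtype=float)
    n = draws.size
    if n < 2 * n_batches:
        return float(draws.std(ddof=1) / np.sqrt(n))
    size = n // n_batches
    batch_means = draws[: n_batches * size].reshape(n_batches, size).mean(axis=1)
    return float(batch_means.std(ddof=1) / np.sqrt(n_batches))


def sample_m_posterior(
    k: int,
    m: int,
    a: float = 1.0,
    b: float = 1.0,
    n_burn: int = 10_000,
    n_keep: int = 10_000,
    seed: Union[int, np.random.Generator, None] = None,
) -> PrecisionPosteriorSamples:
    """Escobar-West Gibbs sampler for the precision M given k distinct values.

    Parameters
    ----------
    k
        Observed number of distinct values (clusters), 1 <= k <= m.
    m
        Number of DP draws that produced the k distinct values.
    a, b
        Gamma(a, b) prior on M; the default a = b = 1 is the standard
        Exponential(1) prior.
    n_burn, n_keep
        Discarded and retained iterations.  The chain starts at the prior
        mean M0 = a/b and mixes within a few iterations.
    """
    if not 1 <= k <= m:
        raise ValueError("need 1 <= k <= m")
    if not (a > 0 and b > 0):
        raise ValueError("prior shape and rate must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    tiny = np.finfo(float).tiny
    M = a / b
    draws = np.empty(n_keep)
    for it in range(n_burn + n_keep):
        eta = rng.beta(M + 1.0, m)
        eta = min(max(eta, tiny), 1.0 - np.finfo(float).epsneg)
        rate = b - np.log(eta)
        odds = (a + k - 1.0) / (m * rate)
        shape = a + k if rng.random() < odds / (1.0 + odds) else a + k - 1.0
        M = rng.gamma(shape, 1.0 / rate)
        if it >= n_burn:
            draws[it - n_burn] = M
    return PrecisionPosteriorSamples(
        draws=draws, n_burn=n_burn, n_keep=n_keep, prior_shape=a,
        prior_rate=b, k=k, m=m,
        seed=seed if not isinstance(seed, np.random.Generator) else None,
    )


def m_posterior_density_grid(
    k: int, m: int, a: float, b: float, grid: np.ndarray
) -> np.ndarray:
    """Unnormalised log posterior density of M on a grid of positive values.

    log pi(M | k) = log pi(M) + (k - 1) log M + log(M + m) + log B(M+1, m)
    up to a constant, with the Beta function evaluated via log-gamma
    differences (never by numerical integration).
    """
    grid = np.asarray(grid, dtype=float)
    if (grid <= 0).any():
        raise ValueError("grid values must be positive")
    log_prior = (a - 1.0) * np.log(grid) - b * grid
    return (log_prior + (k - 1.0) * np.log(grid) + np.log(grid + m)
            + betaln(grid + 1.0, m))


def m_posterior_grid_moments(
    k: int, m: int, a: float = 1.0, b: float = 1.0,
    grid: Union[np.ndarray, None] = None,
) -> tuple[float, float]:
    """Posterior mean and sd of M by trapezoid quadrature on a grid.

    With no grid supplied, an adaptive one is built by locating the mode
    of the log density on a coarse log-spaced scan and refining +/- 12
    posterior sd around it.
    """
    if grid is None:
        coarse = np.logspace(-4, np.log10(20.0 * m + 10.0), 4000)
        ld = m_posterior_density_grid(k, m, a, b, coarse)
        mode = coarse[np.argmax(ld)]
        # local curvature -> rough sd for window sizing
        h = mode * 1e-3 + 1e-6
        pts = np.array([mode - h, mode, mode + h])
        d2 = np.diff(m_posterior_density_grid(k, m, a, b, pts), 2)[0] / h**2
        sd0 = 1.0 / np.sqrt(-d2) if d2 < 0 else mode
        lo = max(mode - 12.0 * sd0, 1e-8)
        grid = np.linspace(lo, mode + 12.0 * sd0, 20_001)
    ld = m_posterior_density_grid(k, m, a, b, grid)
    w = np.exp(ld - ld.max())
    z = np.trapezoid(w, grid)
    mean = float(np.trapezoid(grid * w, grid) / z)
    var = float(np.trapezoid((grid - mean) ** 2 * w, grid) / z)
    return mean, float(np.sqrt(var))
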