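"""Dirichlet-process sensitivity analysis of step-up multiple testing.

Every probability measure nu on the integer bins (r-1, r] induces, through
its shape function, a step-up procedure with distribution-free FDR control
(see :mod:`dpmtp.nu_measures`).  Placing a Dirichlet-process prior
``nu ~ DP(M * nu0)`` on nu therefore places a prior on the *space of such
procedures*: by Ferguson's definition the bin masses of one draw follow

    (nu_1, ..., nu_m) ~ Dirichlet_m(M * nu0_1, ..., M * nu0_m),

with baseline nu0 (default: the Benjamini-Yekutieli measure, so the prior
is centred on the BY procedure) and precision M (fixed, or integrated over
a standard Exponential(1) hyperprior).  Monte-Carlo draws of nu propagate
to draws of the discovery count R, whose spread quantifies how sensitive
the "how many of the smallest p-values are significant?" decision is to
the choice of procedure; the per-hypothesis *significance probability* is
the fraction of draws in which that hypothesis's rank falls at or below R.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .nu_measures import BinnedMeasure, by_baseline_measure
from .pvalue_data import PValueFamily

__all__ = [
    "DPSpec",
    "SensitivityResult",
    "sample_dirichlet_measure",
    "dp_mtp_run",
    "expected_clusters",
    "expected_clusters_bounds",
]

EXP1 = "exponential(1)"
_MAX_RETRIES = 100
_QUANTILES = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class DPSpec:
    """Configuration of one DP sensitivity run.

    ``mass`` is either a fixed positive precision M or the string
    ``"exponential(1)"`` to integrate over the standard exponential
    hyperprior (the default, which favours small M and hence large prior
    spread of nu around the baseline).
    """

    baseline: Optional[BinnedMeasure] = None  # None -> BY baseline for m
    mass: Union[float, str] = EXP1
    n_draws: int = 1000
    alpha: float = 0.05
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if isinstance(self.mass, str):
            if self.mass.lower() != EXP1:
                raise ValueError(f"mass must be positive or {EXP1!r}")
            object.__setattr__(self, "mass", EXP1)
        elif not self.mass > 0:
            raise ValueError("fixed mass must be > 0")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class SensitivityResult:
    """Per-draw discovery counts, precision draws and significance probabilities."""

    R_draws: np.ndarray     # int, one per draw
    M_draws: np.ndarray     # float, one per draw
    sig_prob: np.ndarray    # per hypothesis, original order
    alpha: float
    n_draws: int
    seed: Optional[int]

    @property
    def mean_R(self) -> float:
        return float(self.R_draws.mean())

    @property
    def sd_R(self) -> float:
        return float(self.R_draws.std(ddof=1)) if self.n_draws > 1 else 0.0

    @property
    def quantiles_R(self) -> dict[float, float]:
        qs = np.quantile(self.R_draws, _QUANTILES)
        return {q: float(v) for q, v in zip(_QUANTILES, qs)}

    def summary(self) -> dict:
        return {
            "mean_R": self.mean_R,
            "sd_R": self.sd_R,
            "quantiles_R": {f"{int(q * 100)}%": v
                            for q, v in self.quantiles_R.items()},
            "alpha": self.alpha,
            "n_draws": self.n_draws,
            "seed": self.seed,
        }

    def histogram(self, n_bins: int = 30) -> "np.ndarray":
        """Histogram of R_draws as a (bin_left, bin_right, count) array."""
        counts, edges = np.histogram(self.R_draws, bins=n_bins)
        return np.column_stack([edges[:-1], edges[1:], counts])


def sample_dirichlet_measure(
    baseline: BinnedMeasure,
    mass_value: float,
    rng: np.random.Generator,
) -> BinnedMeasure:
    """One draw of (nu_1, ..., nu_m) ~ Dirichlet_m(M * nu0_1, ..., M * nu0_m).

    Sampled via independent Gamma(M * nu0_r, 1) components normalised by
    their sum.  With small M the concentrations can be far below 1 and
    individual components underflow to exact zero; the draw is valid as
    long as the sum is positive, and is retried (up to 100 times) if the
    whole vector underflows.
    """
    if not mass_value > 0:
        raise ValueError("mass_value must be > 0")
    conc = mass_value * baseline.mass
    for _ in range(_MAX_RETRIES):
        g = rng.gamma(shape=conc)
        total = g.sum()
        if total > 0:
            return BinnedMeasure(g / total)
    raise FloatingPointError(
        "Dirichlet draw underflowed to zero repeatedly; "
        "consider a larger precision M"
    )


def _discovery_count(sorted_p: np.ndarray, nu_mass: np.ndarray,
                     alpha: float) -> int:
    """Step-up count for the schedule induced by nu (single O(m) scan)."""
    m = sorted_p.size
    beta = np.cumsum(np.arange(1, m + 1) * nu_mass)
    delta = np.minimum(alpha * beta / m, 1.0)
    passed = np.nonzero(sorted_p <= delta)[0]
    return int(passed[-1]) + 1 if passed.size else 0


def dp_mtp_run(family: PValueFamily, spec: DPSpec) -> SensitivityResult:
    """Run the DP sensitivity analysis on a family of p-values.

    For each of ``spec.n_draws`` draws: sample M (fixed value, or one
    Exponential(1) variate per draw under the hyperprior), sample
    nu ~ Dirichlet(M * nu0), build the induced step-up thresholds
    ``Delta(r) = alpha * beta_nu(r) / m`` and record the discovery count
    R.  The significance probability of the hypothesis of rank r is the
    proportion of draws with ``r <= R``; since the events {r <= R} are
    nested, it is non-increasing in rank.  Tied p-values straddling the
    rank-R boundary may receive different probabilities (rank-based rule).
    """
    m = family.m
    baseline = spec.baseline if spec.baseline is not None \
        else by_baseline_measure(m)
    if baseline.m != m:
        raise ValueError("baseline measure size must equal family size")
    rng = np.random.default_rng(spec.seed)
    sorted_p = family.sorted_values

    R_draws = np.empty(spec.n_draws, dtype=np.int64)
    M_draws = np.empty(spec.n_draws)
    for i in range(spec.n_draws):
        if spec.mass == EXP1:
            M = rng.exponential(1.0)
            while M <= 0.0:  # exact-zero exponential draw; essentially never
                M = rng.exponential(1.0)
        else:
            M = float(spec.mass)
        nu = sample_dirichlet_measure(baseline, M, rng)
        R_draws[i] = _discovery_count(sorted_p, nu.mass, spec.alpha)
        M_draws[i] = M

    # sig_prob by rank: fraction of draws with R >= rank, mapped back to
    # original order through the sort permutation.
    counts = np.bincount(R_draws, minlength=m + 1)
    ge_rank = np.cumsum(counts[::-1])[::-1]  # ge_rank[r] = #draws with R >= r
    sig_by_rank = ge_rank[1:] / spec.n_draws
    sig_prob = np.empty(m)
    sig_prob[family.order] = sig_by_rank
    return SensitivityResult(
        R_draws=R_draws, M_draws=M_draws, sig_prob=sig_prob,
        alpha=spec.alpha, n_draws=spec.n_draws, seed=spec.seed,
    )


def expected_clusters(mass_value: float, m: int) -> float:
    """Expected number of distinct values among m draws from a DP(M * nu0).

    ``sum_{i=1}^m M / (M + i - 1)`` — the Chinese-restaurant-process
    expectation, used to elicit the precision M:  M = 1/m gives about one
    cluster, M = m^2 about m clusters (essentially i.i.d. draws from nu0).
    """
    if not mass_value > 0:
        raise ValueError("mass_value must be > 0")
    if m < 1:
        raise ValueError("m must be >= 1")
    i = np.arange(1, m + 1, dtype=float)
    return float(np.sum(mass_value / (mass_value + i - 1)))


def expected_clusters_bounds(mass_value: float, m: int) -> tuple[float, float]:
    """Bracketing interval [max{1, M log((M+m)/M)}, 1 + M log((M+m+1)/M)]."""
    M = float(mass_value)
    lower = max(1.0, M * np.log((M + m) / M))
    upper = 1.0 + M * np.log((M + m + 1) / M)
    return lower, upper
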