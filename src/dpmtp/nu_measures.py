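"""Binned probability measures nu and their step-up shape functions.

A step-up procedure with thresholds ``Delta(r) = alpha * beta_nu(r) / m``
controls FDR at level ``pi0 * alpha`` under *arbitrary* dependence between
p-values whenever ``beta_nu(r) = sum_{j<=r} j * nu_j`` for some probability
measure nu on the integer bins (r-1, r], r = 1..m.  The Benjamini-Yekutieli
procedure is the special case ``nu_r = 1 / (r * H_m)`` (H_m the m-th
harmonic number), whose shape function is linear: ``beta(r) = r / H_m``.

These measures are the random object of the Dirichlet-process sensitivity
analysis; this module provides the deterministic building blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .classical_mtps import ThresholdSchedule

__all__ = [
    "BinnedMeasure",
    "harmonic_number",
    "by_baseline_measure",
    "shape_function",
    "threshold_schedule",
]

_MASS_TOL = 1e-9


@dataclass(frozen=True)
class BinnedMeasure:
    """A probability measure on the bins (r-1, r], r = 1..m.

    ``mass[r-1]`` is the probability of bin r; masses are nonnegative and
    sum to one within 1e-9.
    """

    mass: np.ndarray

    def __post_init__(self) -> None:
        mass = np.asarray(self.mass, dtype=float)
        if mass.ndim != 1 or mass.size < 1:
            raise ValueError("measure needs at least one bin")
        if (mass < 0).any():
            raise ValueError("bin masses must be nonnegative")
        if abs(mass.sum() - 1.0) > _MASS_TOL:
            raise ValueError(f"bin masses must sum to 1, got {mass.sum()!r}")
        object.__setattr__(self, "mass", mass)

    @property
    def m(self) -> int:
        return int(self.mass.size)

    def to_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(
            {"bin": np.arange(1, self.m + 1), "mass": self.mass}
        ).to_csv(path, index=False)


def harmonic_number(m: int) -> float:
    """H_m = sum_{j=1}^m 1/j by direct summation."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(np.sum(1.0 / np.arange(1, m + 1)))


def by_baseline_measure(m: int) -> BinnedMeasure:
    """The measure with mass 1/(r * H_m) on bin r: the BY baseline nu0.

    Its shape function is ``beta(r) = r / H_m``, reproducing the
    Benjamini-Yekutieli thresholds; it is the default baseline of the
    Dirichlet-process prior.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    r = np.arange(1, m + 1)
    return BinnedMeasure(1.0 / (r * harmonic_number(m)))


def shape_function(nu: BinnedMeasure) -> np.ndarray:
    """beta_nu(r) = sum_{j=1}^r j * nu_j, the cumulative first-moment transform.

    Non-decreasing with beta(m) <= m; scaling by alpha/m yields step-up
    thresholds with distribution-free FDR control.
    """
    j = np.arange(1, nu.m + 1)
    return np.cumsum(j * nu.mass)


def threshold_schedule(
    beta: np.ndarray, alpha: float, m: int, method_name: str = "nu-step-up"
) -> ThresholdSchedule:
    """Step-up schedule Delta(r) = alpha * beta(r) / m, clipped to [0, 1]."""
    beta = np.asarray(beta, dtype=float)
    if beta.size != m:
        raise ValueError("beta length must equal m")
    if (np.diff(beta) < -1e-12).any():
        raise ValueError("shape function must be non-decreasing")
    delta = np.clip(alpha * beta / m, 0.0, 1.0)
    return ThresholdSchedule(np.maximum.accumulate(delta), alpha,
                             "step_up", method_name)
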