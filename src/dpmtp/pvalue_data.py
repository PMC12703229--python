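"""P-value families: containers, file I/O, and a dependent-p-value simulator.

A *family* is the vector of m marginal p-values produced by m hypothesis
tests.  All procedures in this package operate on the order statistics
``p_(1) <= ... <= p_(m)``, so the family carries a stable ascending sort
permutation alongside the values in their original order.

The simulator draws p-values from an equicorrelated Gaussian one-factor
model: true nulls are marginally Uniform[0,1] (hence super-uniform, the
validity condition for every procedure here), alternatives are
stochastically smaller via a positive mean shift of the latent normal.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PValueFamily",
    "TruthLabels",
    "load_pvalues",
    "save_pvalues",
    "simulate_pvalues",
    "distinct_count",
]


@dataclass(frozen=True)
class PValueFamily:
    """An ordered family of m marginal p-values.

    Parameters
    ----------
    values
        P-values in original hypothesis order, each in [0, 1].
    labels
        Optional identifier per hypothesis (same length as ``values``).

    Attributes
    ----------
    order
        Stable ascending sort permutation: ``order[r]`` is the original
        index of the rank-(r+1) p-value, so ``values[order]`` is
        non-decreasing.  Ties keep original input order.
    """

    values: np.ndarray
    labels: Optional[Sequence[str]] = None
    order: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("a p-value family needs at least one value")
        if np.isnan(values).any():
            raise ValueError("p-values must not contain NaN")
        if (values < 0).any() or (values > 1).any():
            bad = values[(values < 0) | (values > 1)][0]
            raise ValueError(f"p-value {bad!r} outside [0, 1]")
        if self.labels is not None and len(self.labels) != values.size:
            raise ValueError("labels length must match number of p-values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "order", np.argsort(values, kind="stable"))

    @property
    def m(self) -> int:
        return int(self.values.size)

    @property
    def sorted_values(self) -> np.ndarray:
        """Order statistics p_(1) <= ... <= p_(m)."""
        return self.values[self.order]


@dataclass(frozen=True)
class TruthLabels:
    """Ground-truth null/alternative status for a simulated family."""

    is_true_null: np.ndarray

    def __post_init__(self) -> None:
        flags = np.asarray(self.is_true_null, dtype=bool)
        object.__setattr__(self, "is_true_null", flags)

    @property
    def m(self) -> int:
        return int(self.is_true_null.size)

    @property
    def m0(self) -> int:
        """Number of true null hypotheses."""
        return int(self.is_true_null.sum())

    @property
    def m1(self) -> int:
        return self.m - self.m0

    @property
    def pi0(self) -> float:
        """Proportion of true nulls, m0/m."""
        return self.m0 / self.m


def load_pvalues(
    path: Union[str, Path, io.IOBase], column: Optional[str] = None
) -> PValueFamily:
    """Read a p-value family from plain text or a delimited table.

    The dialect is auto-detected: a file whose first line parses as a
    single number is treated as one-p-value-per-line text; otherwise it is
    read as a delimited table (separator sniffed) and the designated
    ``column`` (default ``"p"``) supplies the values.  Row labels are taken
    from a ``label`` column when present.

    Raises
    ------
    ValueError
        On an empty file, a non-numeric entry (the offending line is
        named), or a value outside [0, 1].
    """
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
    else:
        text = path.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty p-value file")

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    if _is_number(lines[0].strip()) and column is None:
        values = np.empty(len(lines))
        for i, ln in enumerate(lines):
            tok = ln.strip()
            if not _is_number(tok):
                raise ValueError(f"non-numeric p-value {tok!r} on line {i + 1}")
            values[i] = float(tok)
        return PValueFamily(values)

    df = pd.read_csv(io.StringIO(text), sep=None, engine="python")
    col = column if column is not None else "p"
    if col not in df.columns:
        raise ValueError(
            f"column {col!r} not found; available: {list(df.columns)}"
        )
    raw = pd.to_numeric(df[col], errors="coerce")
    if raw.isna().any():
        line = int(raw.index[raw.isna()][0]) + 2  # +1 header, +1 one-based
        raise ValueError(f"non-numeric p-value on line {line}")
    labels = df["label"].astype(str).tolist() if "label" in df.columns else None
    return PValueFamily(raw.to_numpy(dtype=float), labels=labels)


def save_pvalues(
    family: PValueFamily,
    path: Union[str, Path],
    truth: Optional[TruthLabels] = None,
) -> None:
    """Write a family (and optional truth flags) as CSV with a ``p`` column."""
    data = {"p": family.values}
    if family.labels is not None:
        data = {"label": list(family.labels), "p": family.values}
    if truth is not None:
        data["true_null"] = truth.is_true_null
    pd.DataFrame(data).to_csv(path, index=False)


def simulate_pvalues(
    m: int,
    pi0: float = 0.8,
    effect: float = 3.0,
    rho: float = 0.0,
    seed: Union[int, np.random.Generator, None] = None,
) -> tuple[PValueFamily, TruthLabels]:
    """Simulate m dependent p-values with known truth labels.

    Latent variates follow the exchangeable one-factor construction
    ``X_i = sqrt(rho) * Z0 + sqrt(1 - rho) * Z_i`` with ``Z0, Z_i`` i.i.d.
    standard normal, so every pair of latents has correlation ``rho``.
    Each hypothesis is a true null with probability ``pi0`` (independent
    seeded draws).  Null p-values are the upper-tail probability
    ``1 - Phi(X_i)``, exactly Uniform[0,1] marginally; alternatives shift
    the latent by ``+effect`` first, making their p-values stochastically
    smaller.

    Parameters
    ----------
    m
        Number of hypotheses (>= 1).
    pi0
        Probability each hypothesis is a true null, in [0, 1].
    effect
        Mean shift of the latent normal under the alternative; larger
        means smaller alternative p-values.
    rho
        Equicorrelation of the latent normals, in [0, 1).  Negative
        equicorrelation is not representable by a single shared factor.
    seed
        Integer seed or ``numpy.random.Generator``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 <= pi0 <= 1:
        raise ValueError("pi0 must lie in [0, 1]")
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    is_null = rng.random(m) < pi0
    z0 = rng.standard_normal()
    z = rng.standard_normal(m)
    latent = np.sqrt(rho) * z0 + np.sqrt(1.0 - rho) * z
    latent = latent + np.where(is_null, 0.0, effect)
    values = stats.norm.sf(latent)
    return PValueFamily(values), TruthLabels(is_null)


def distinct_count(family: PValueFamily) -> int:
    """Number of distinct p-values (exact floating comparison).

    Used as the cluster count k when eliciting the Dirichlet-process
    precision parameter from observed p-values.
    """
    return int(np.unique(family.values).size)
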