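"""Error tallies and Monte-Carlo FWER/FDR estimation for simulation studies.

The 2x2 cross-tabulation of rejection decisions against true null status
yields the false discovery proportion FDP = V / max(R, 1); its expectation
over replicated datasets is the FDR, and the probability of V >= 1 is the
FWER.  Replicate families are generated with seeds spawned from a single
master seed so that different procedures can be compared on identical
data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .classical_mtps import MTPDecision
from .pvalue_data import PValueFamily, TruthLabels, simulate_pvalues

__all__ = [
    "ErrorTally",
    "tally",
    "estimate_fdr",
    "estimate_fwer",
    "evaluate_procedures",
]

Procedure = Callable[[PValueFamily], MTPDecision]


@dataclass(frozen=True)
class ErrorTally:
    """Counts of the four test outcomes for one decision on one dataset.

    V: false discoveries, S: true discoveries, U: true non-discoveries,
    T: false non-discoveries.  Identities: V + S = R, U + T = m - R,
    V + U = m0, S + T = m1.
    """

    V: int
    S: int
    U: int
    T: int

    @property
    def R(self) -> int:
        return self.V + self.S

    @property
    def fdp(self) -> float:
        """False discovery proportion V / max(R, 1)."""
        return self.V / max(self.R, 1)


def tally(decision: MTPDecision, truth: TruthLabels) -> ErrorTally:
    """Cross-tabulate rejections against true-null flags."""
    if decision.m != truth.m:
        raise ValueError("decision and truth must have equal length")
    rej = decision.rejected
    null = truth.is_true_null
    return ErrorTally(
        V=int(np.count_nonzero(rej & null)),
        S=int(np.count_nonzero(rej & ~null)),
        U=int(np.count_nonzero(~rej & null)),
        T=int(np.count_nonzero(~rej & ~null)),
    )


def _replicate_rngs(n_reps: int, seed) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n_reps)]


def evaluate_procedures(
    procedures: dict[str, Procedure],
    m: int,
    pi0: float,
    effect: float,
    rho: float,
    n_reps: int,
    seed: Optional[int] = None,
) -> dict[str, dict[str, float]]:
    """Monte-Carlo FDR, FWER and power of several procedures on shared data.

    Each of ``n_reps`` replicate families (see
    :func:`dpmtp.pvalue_data.simulate_pvalues`) is analysed by every
    procedure, so procedures are compared on identical data.  Returns, per
    procedure: ``fdr``, ``fdr_se``, ``fwer``, ``fwer_se``, ``power``
    (mean S/m1 over replicates with m1 > 0) and ``power_se``; standard
    errors are sd / sqrt(n_reps).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    fdp = {name: np.empty(n_reps) for name in procedures}
    any_false = {name: np.empty(n_reps) for name in procedures}
    power = {name: [] for name in procedures}
    for i, rng in enumerate(_replicate_rngs(n_reps, seed)):
        family, truth = simulate_pvalues(m, pi0, effect, rho, seed=rng)
        for name, proc in procedures.items():
            t = tally(proc(family), truth)
            fdp[name][i] = t.fdp
            any_false[name][i] = 1.0 if t.V >= 1 else 0.0
            if truth.m1 > 0:
                power[name].append(t.S / truth.m1)
    out: dict[str, dict[str, float]] = {}
    for name in procedures:
        pw = np.asarray(power[name]) if power[name] else np.zeros(1)
        out[name] = {
            "fdr": float(fdp[name].mean()),
            "fdr_se": float(fdp[name].std(ddof=1) / np.sqrt(n_reps)),
            "fwer": float(any_false[name].mean()),
            "fwer_se": float(any_false[name].std(ddof=1) / np.sqrt(n_reps)),
            "power": float(pw.mean()),
            "power_se": float(pw.std(ddof=1) / np.sqrt(pw.size))
            if pw.size > 1 else 0.0,
        }
    return out


def estimate_fdr(
    procedure: Procedure,
    m: int,
    pi0: float = 1.0,
    effect: float = 0.0,
    rho: float = 0.0,
    n_reps: int = 1000,
    seed: Optional[int] = None,
) -> tuple[float, float]:
    """Mean FDP over replicated simulated families, with its standard error."""
    res = evaluate_procedures({"_": procedure}, m, pi0, effect, rho,
                              n_reps, seed)["_"]
    return res["fdr"], res["fdr_se"]


def estimate_fwer(
    procedure: Procedure,
    m: int,
    pi0: float = 1.0,
    effect: float = 0.0,
    rho: float = 0.0,
    n_reps: int = 1000,
    seed: Optional[int] = None,
) -> tuple[float, float]:
    """Fraction of replicates with at least one false discovery, with SE."""
    res = evaluate_procedures({"_": procedure}, m, pi0, effect, rho,
                              n_reps, seed)["_"]
    return res["fwer"], res["fwer_se"]
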