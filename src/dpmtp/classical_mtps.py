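"""Classical multiple testing procedures and the step-up/step-down engines.

Six benchmark procedures are provided: Bonferroni, weighted Bonferroni,
Sidak, Holm (FWER control under arbitrary dependence), Benjamini-Hochberg
(FDR control under independence/PRDS) and Benjamini-Yekutieli (FDR control
under arbitrary dependence).  Each is expressed through a per-rank
``ThresholdSchedule`` and one of three generic engines:

* single-step: reject every hypothesis whose p-value is below a constant
  (or per-hypothesis) threshold;
* step-up: ``R = max{r : p_(r) <= delta_r}`` with ``p_(0) = 0``, reject
  the R smallest p-values;
* step-down: test sorted p-values sequentially, stop at the first rank
  whose p-value exceeds its threshold.

A decision reports the discovery count R and per-hypothesis rejection
flags in original input order.  The rejection set is rank-based: when the
boundary p-value p_(R) is tied with p_(R+1), rejection follows the stable
sort rank, so tied boundary values may split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .pvalue_data import PValueFamily

__all__ = [
    "ThresholdSchedule",
    "MTPDecision",
    "step_up",
    "step_down",
    "single_step",
    "bonferroni",
    "weighted_bonferroni",
    "weighted_bonferroni_sensitivity",
    "holm",
    "sidak",
    "bh",
    "by",
    "bh_schedule",
    "by_schedule",
    "holm_schedule",
]

KINDS = ("step_up", "step_down", "single_step")


@dataclass(frozen=True)
class ThresholdSchedule:
    """Per-rank thresholds ``delta[r-1] = Delta_alpha(H_(r))``, r = 1..m."""

    delta: np.ndarray
    alpha: float
    kind: str
    method_name: str = ""

    def __post_init__(self) -> None:
        delta = np.asarray(self.delta, dtype=float)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if (delta < 0).any() or (delta > 1).any():
            raise ValueError("thresholds must lie in [0, 1]")
        if self.kind in ("step_up", "step_down") and (np.diff(delta) < 0).any():
            raise ValueError(f"{self.kind} thresholds must be non-decreasing")
        object.__setattr__(self, "delta", delta)

    @property
    def m(self) -> int:
        return int(self.delta.size)


@dataclass(frozen=True)
class MTPDecision:
    """Outcome of one procedure: discovery count and rejection flags."""

    R: int
    rejected: np.ndarray  # boolean, original hypothesis order
    method_name: str
    alpha: float
    thresholds: Optional[ThresholdSchedule] = None

    def __post_init__(self) -> None:
        rejected = np.asarray(self.rejected, dtype=bool)
        if int(rejected.sum()) != self.R:
            raise ValueError("R must equal the number of rejected flags")
        object.__setattr__(self, "rejected", rejected)

    @property
    def m(self) -> int:
        return int(self.rejected.size)


def _decision_from_count(
    family: PValueFamily,
    R: int,
    name: str,
    alpha: float,
    schedule: Optional[ThresholdSchedule],
) -> MTPDecision:
    rejected = np.zeros(family.m, dtype=bool)
    rejected[family.order[:R]] = True
    return MTPDecision(R=R, rejected=rejected, method_name=name,
                       alpha=alpha, thresholds=schedule)


def step_up(family: PValueFamily, schedule: ThresholdSchedule) -> MTPDecision:
    """Step-up rule: R = max{r in 0..m : p_(r) <= delta_r}, p_(0) = 0."""
    if schedule.kind != "step_up":
        raise ValueError("schedule kind must be 'step_up'")
    if schedule.m != family.m:
        raise ValueError("schedule length must equal number of p-values")
    passed = np.nonzero(family.sorted_values <= schedule.delta)[0]
    R = int(passed[-1]) + 1 if passed.size else 0
    return _decision_from_count(family, R, schedule.method_name,
                                schedule.alpha, schedule)


def step_down(family: PValueFamily, schedule: ThresholdSchedule) -> MTPDecision:
    """Step-down rule: reject while p_(r) <= delta_r, stop at first failure."""
    if schedule.kind != "step_down":
        raise ValueError("schedule kind must be 'step_down'")
    if schedule.m != family.m:
        raise ValueError("schedule length must equal number of p-values")
    fails = np.nonzero(family.sorted_values > schedule.delta)[0]
    R = int(fails[0]) if fails.size else family.m
    return _decision_from_count(family, R, schedule.method_name,
                                schedule.alpha, schedule)


def single_step(
    family: PValueFamily,
    threshold: Union[float, np.ndarray],
    alpha: float,
    name: str,
) -> MTPDecision:
    """Reject every hypothesis with p_i <= threshold (scalar or per-i)."""
    thr = np.broadcast_to(np.asarray(threshold, dtype=float), (family.m,))
    rejected = family.values <= thr
    return MTPDecision(R=int(rejected.sum()), rejected=rejected,
                       method_name=name, alpha=alpha, thresholds=None)


# --- schedules -------------------------------------------------------------

def bh_schedule(m: int, alpha: float) -> ThresholdSchedule:
    """Benjamini-Hochberg: Delta(r) = alpha * r / m (shape beta(r) = r)."""
    r = np.arange(1, m + 1)
    return ThresholdSchedule(alpha * r / m, alpha, "step_up", "BH")


def by_schedule(m: int, alpha: float) -> ThresholdSchedule:
    """Benjamini-Yekutieli: BH thresholds divided by the harmonic number H_m."""
    r = np.arange(1, m + 1)
    h_m = np.sum(1.0 / r)
    return ThresholdSchedule(alpha * r / (m * h_m), alpha, "step_up", "BY")


def holm_schedule(m: int, alpha: float) -> ThresholdSchedule:
    """Holm: Delta(r) = alpha / (m - r + 1)."""
    r = np.arange(1, m + 1)
    return ThresholdSchedule(alpha / (m - r + 1), alpha, "step_down", "Holm")


# --- procedures ------------------------------------------------------------

def bonferroni(family: PValueFamily, alpha: float = 0.05) -> MTPDecision:
    """Bonferroni: reject where p_i <= alpha / m.  Strong FWER control."""
    _check_alpha(alpha)
    return single_step(family, alpha / family.m, alpha, "Bonferroni")


def weighted_bonferroni(
    family: PValueFamily, weights: np.ndarray, alpha: float = 0.05
) -> MTPDecision:
    """Weighted Bonferroni: reject where p_i <= alpha * w_i.

    Weights are paired with hypotheses in original input order, must be
    nonnegative and sum to one (union bound gives FWER <= alpha for any
    such weights, under arbitrary dependence).
    """
    _check_alpha(alpha)
    w = np.asarray(weights, dtype=float)
    if w.size != family.m:
        raise ValueError("weights length must equal number of p-values")
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be nonnegative and sum to 1")
    return single_step(family, alpha * w, alpha, "weighted Bonferroni")


def weighted_bonferroni_sensitivity(
    family: PValueFamily,
    alpha: float = 0.05,
    n_draws: int = 1000,
    seed: Union[int, np.random.Generator, None] = None,
) -> tuple[float, float, np.ndarray]:
    """Discovery-count distribution under flat-Dirichlet random weights.

    Draws ``n_draws`` weight vectors from Dirichlet_m(1, ..., 1), applies
    the weighted Bonferroni rule to each, and returns the sample mean,
    sample standard deviation (denominator n_draws - 1) and the per-draw
    discovery counts.
    """
    _check_alpha(alpha)
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    rng = np.random.default_rng(seed)
    p = family.values
    R = np.empty(n_draws, dtype=np.int64)
    for i in range(n_draws):
        w = rng.dirichlet(np.ones(family.m))
        R[i] = int(np.count_nonzero(p <= alpha * w))
    return float(R.mean()), float(R.std(ddof=1)), R


def holm(family: PValueFamily, alpha: float = 0.05) -> MTPDecision:
    """Holm step-down procedure.  Strong FWER control, dominates Bonferroni."""
    _check_alpha(alpha)
    return step_down(family, holm_schedule(family.m, alpha))


def sidak(family: PValueFamily, alpha: float = 0.05) -> MTPDecision:
    """Sidak: reject where p_i <= 1 - (1 - alpha)^(1/m).

    Exact FWER control for independent p-values; conservative under
    positive dependence.
    """
    _check_alpha(alpha)
    thr = 1.0 - (1.0 - alpha) ** (1.0 / family.m)
    return single_step(family, thr, alpha, "Sidak")


def bh(family: PValueFamily, alpha: float = 0.05) -> MTPDecision:
    """Benjamini-Hochberg step-up procedure (pi0 fixed at 1)."""
    _check_alpha(alpha)
    return step_up(family, bh_schedule(family.m, alpha))


def by(family: PValueFamily, alpha: float = 0.05) -> MTPDecision:
    """Benjamini-Yekutieli step-up procedure.

    FDR <= pi0 * alpha under arbitrary dependence between p-values.
    """
    _check_alpha(alpha)
    return step_up(family, by_schedule(family.m, alpha))


def _check_alpha(alpha: float) -> None:
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
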