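"""Uncertainty-threshold triage of probable high-error area estimates.

Given per-case uncertainty values and absolute percent errors against a
reference, a case is *flagged* for expert review when its uncertainty is
strictly above a threshold, and counted *high-error* when its absolute error
strictly exceeds the cutoff (2.5% by default). Treating high-error as the
positive class yields an operating point per threshold: flagged fraction,
the threshold's percentile rank, and sensitivity/specificity. Thresholds can
be set by a quantile of the uncertainty distribution or selected on a
labeled validation split under an explicit policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "OperatingPoint",
    "TriageConfig",
    "quantile_threshold",
    "evaluate",
    "operating_curve",
    "select_threshold",
]

DEFAULT_ERROR_CUTOFF = 2.5  # percent SMA difference defining a high-error case


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    flagged_fraction: float
    threshold_percentile: float  # fraction of cases at or below the threshold
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float  # NaN when no high-error cases exist
    specificity: float  # NaN when no low-error cases exist

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass(frozen=True)
class TriageConfig:
    error_cutoff: float = DEFAULT_ERROR_CUTOFF
    policy: Literal["quantile", "max_youden", "sensitivity_floor", "review_budget"] = "max_youden"
    policy_parameter: float = math.nan

    def __post_init__(self) -> None:
        if self.error_cutoff <= 0:
            raise ValueError("error_cutoff must be positive")


def quantile_threshold(uncertainties: Sequence[float], q: float) -> float:
    """Nearest-rank quantile of the uncertainty values.

    The threshold is the ceil(q·n)-th smallest value, so the fraction of
    values strictly above it is at most 1 − q.
    """
    if not (0.0 < q < 1.0):
        raise ValueError(f"q must lie strictly between 0 and 1, got {q}")
    vals = np.sort(np.asarray(uncertainties, dtype=np.float64))
    if vals.size == 0:
        raise ValueError("empty uncertainty vector")
    rank = math.ceil(q * vals.size)  # 1-based nearest rank
    return float(vals[rank - 1])


def evaluate(
    uncertainties: Sequence[float],
    abs_errors: Sequence[float],
    threshold: float,
    error_cutoff: float = DEFAULT_ERROR_CUTOFF,
) -> OperatingPoint:
    """Evaluate one uncertainty threshold against reference errors.

    Flagged iff uncertainty > threshold (strict); high-error iff
    |error| > cutoff (strict). Sensitivity/specificity with a zero
    denominator are NaN, never 0 or 1 by convention.
    """
    u = np.asarray(uncertainties, dtype=np.float64)
    e = np.abs(np.asarray(abs_errors, dtype=np.float64))
    if u.shape != e.shape or u.ndim != 1:
        raise ValueError("uncertainties and errors must be equal-length 1-D vectors")
    if u.size == 0:
        raise ValueError("empty inputs")
    flagged = u > threshold
    high = e > error_cutoff
    tp = int((flagged & high).sum())
    fp = int((flagged & ~high).sum())
    fn = int((~flagged & high).sum())
    tn = int((~flagged & ~high).sum())
    n = u.size
    return OperatingPoint(
        threshold=float(threshold),
        flagged_fraction=float(flagged.sum()) / n,
        threshold_percentile=float((~flagged).sum()) / n,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=tp / (tp + fn) if (tp + fn) > 0 else math.nan,
        specificity=tn / (tn + fp) if (tn + fp) > 0 else math.nan,
    )


def operating_curve(
    uncertainties: Sequence[float],
    abs_errors: Sequence[float],
    candidate_thresholds: Sequence[float],
    error_cutoff: float = DEFAULT_ERROR_CUTOFF,
) -> list[OperatingPoint]:
    """One operating point per candidate threshold, ascending by threshold."""
    if len(candidate_thresholds) == 0:
        raise ValueError("need at least one candidate threshold")
    return [
        evaluate(uncertainties, abs_errors, t, error_cutoff)
        for t in sorted(float(t) for t in candidate_thresholds)
    ]


def select_threshold(curve: Sequence[OperatingPoint], config: TriageConfig) -> float:
    """Pick a threshold from an operating curve under an explicit policy.

    * ``max_youden`` — maximize sensitivity + specificity − 1;
    * ``sensitivity_floor`` — smallest threshold whose sensitivity meets the
      floor (errs toward flagging more);
    * ``review_budget`` — the threshold flagging the largest fraction that
      still fits the budget (smallest feasible threshold);
    * ``quantile`` — treated as a review budget of 1 − q on the curve.

    Ties always break toward the lower threshold (more conservative: more
    cases go to review).
    """
    if not curve:
        raise ValueError("empty operating curve")
    pts = sorted(curve, key=lambda p: p.threshold)
    if config.policy == "max_youden":
        finite = [p for p in pts if not math.isnan(p.youden)]
        if not finite:
            raise ValueError("Youden index undefined at every point (single-class errors)")
        best = max(finite, key=lambda p: p.youden)
        # ties toward the lower threshold
        for p in finite:
            if p.youden == best.youden:
                return p.threshold
    if config.policy == "sensitivity_floor":
        feasible = [p for p in pts if not math.isnan(p.sensitivity) and p.sensitivity >= config.policy_parameter]
        if not feasible:
            best_sens = max((p.sensitivity for p in pts if not math.isnan(p.sensitivity)), default=math.nan)
            raise ValueError(
                f"no threshold reaches sensitivity {config.policy_parameter}; best achievable is {best_sens}"
            )
        return min(feasible, key=lambda p: p.threshold).threshold
    if config.policy in ("review_budget", "quantile"):
        budget = config.policy_parameter if config.policy == "review_budget" else 1.0 - config.policy_parameter
        feasible = [p for p in pts if p.flagged_fraction <= budget]
        if not feasible:
            raise ValueError(f"no threshold keeps the flagged fraction within {budget}")
        return min(feasible, key=lambda p: p.threshold).threshold
    raise ValueError(f"unknown policy {config.policy!r}")
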