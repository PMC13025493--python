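"""Segmentation- and method-agreement statistics.

Pixel-level agreement between a predicted and a reference mask is summarized
by confusion counts and the Dice / Jaccard overlap scores (reported in
percent). Method-level agreement between paired area measurements uses
Bland–Altman analysis: the mean of the differences (bias) and the 95%
limits of agreement, bias ± 1.96 × sample SD of the differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ensemble import BinaryMask

__all__ = [
    "ConfusionCounts",
    "AgreementReport",
    "BlandAltmanResult",
    "confusion",
    "dice",
    "jaccard",
    "agreement_report",
    "bland_altman",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class AgreementReport:
    dice: float  # %
    jaccard: float  # %
    fp: int
    fn: int
    signed_diff: float  # %


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    n: int


def confusion(pred: BinaryMask, ref: BinaryMask) -> ConfusionCounts:
    """Pixel-wise confusion counts of a prediction against a reference."""
    if pred.grid.shape != ref.grid.shape:
        raise ValueError(f"mask shapes differ: {pred.grid.shape} vs {ref.grid.shape}")
    p = pred.grid.astype(bool)
    r = ref.grid.astype(bool)
    return ConfusionCounts(
        tp=int((p & r).sum()),
        fp=int((p & ~r).sum()),
        fn=int((~p & r).sum()),
        tn=int((~p & ~r).sum()),
    )


def dice(counts: ConfusionCounts) -> float:
    """Dice overlap in percent: 200·TP / (2·TP + FP + FN); NaN if both masks empty."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        return math.nan
    return 200.0 * counts.tp / denom


def jaccard(counts: ConfusionCounts) -> float:
    """Jaccard index in percent: 100·TP / (TP + FP + FN); NaN if both masks empty."""
    denom = counts.tp + counts.fp + counts.fn
    if denom == 0:
        return math.nan
    return 100.0 * counts.tp / denom


def agreement_report(pred: BinaryMask, ref: BinaryMask) -> AgreementReport:
    """Full per-image agreement row: overlap scores, FP/FN, signed area diff %.

    The signed difference uses the confusion-count identity
    (FP − FN) / (TP + FN) × 100, equal to the percent difference of the two
    pixel counts.
    """
    c = confusion(pred, ref)
    ref_count = c.tp + c.fn
    if ref_count == 0:
        raise ValueError("reference mask is empty; signed area difference undefined")
    return AgreementReport(
        dice=dice(c),
        jaccard=jaccard(c),
        fp=c.fp,
        fn=c.fn,
        signed_diff=(c.fp - c.fn) / ref_count * 100.0,
    )


def bland_altman(paired_values: Sequence[tuple[float, float]]) -> BlandAltmanResult:
    """Bland–Altman agreement of paired (comparator, reference) measurements.

    Differences are comparator − reference; bias is their mean; the 95%
    limits of agreement are bias ± 1.96 × sample (n−1) SD.
    """
    pairs = np.asarray(paired_values, dtype=np.float64)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("expected a sequence of (comparator, reference) pairs")
    if pairs.shape[0] < 2:
        raise ValueError("need at least 2 pairs")
    d = pairs[:, 0] - pairs[:, 1]
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, n=int(d.size))
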