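"""Per-image uncertainty metrics, Platt calibration, and error correlation.

Nine scalar metrics summarize how much an ensemble disagrees about one
slice's segmentation. Probability-style metrics (average predicted-class
probability, its calibrated variant, and the skeletal-muscle-restricted
average probability) capture total uncertainty — they fall as the ensemble
becomes less confident for any reason. Dispersion metrics (coefficients of
variation, variances) capture epistemic uncertainty — they are zero whenever
all members agree exactly, however uncertain the shared prediction is.
Entropy of the mean captures total uncertainty while the expected per-member
entropy isolates the aleatoric part; their gap (mutual information) is the
epistemic remainder, so Jensen's inequality guarantees
``avg_entropy >= expected_entropy``.

Conventions (the source of most cross-tool discrepancies, so they are spelled
out): entropies are base-2 (bits, in [0, 1] per pixel); pixel-wise variance
and SD across members use the population (n) denominator, treating the fixed
finite ensemble as the whole population; the coefficient of variation of
per-member areas uses the sample (n-1) SD, treating members as draws from a
model distribution. Pixels whose across-member mean probability is below
1e-6 are excluded from the pixel-wise CoV (SD/mean is unstable there and the
empty background would otherwise dominate the average).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .ensemble import EnsemblePrediction, ProbabilityMap, member_masks

__all__ = [
    "UncertaintyReport",
    "CalibrationModel",
    "CorrelationResult",
    "compute_metrics",
    "cov_of_areas",
    "fit_platt",
    "apply_platt",
    "correlate",
    "binary_entropy",
    "METRIC_NAMES",
]

#: Pixel-wise CoV eligibility: across-member mean must exceed this.
COV_MEAN_FLOOR = 1e-6
#: Probabilities are clipped into [eps, 1-eps] before the logit transform.
PLATT_CLIP_EPS = 1e-7

METRIC_NAMES = (
    "avg_probability",
    "avg_probability_sm",
    "avg_calibrated_probability",
    "cov_pixelwise",
    "cov_sma",
    "avg_variance",
    "avg_variance_sm",
    "avg_entropy",
    "expected_entropy",
)


@dataclass(frozen=True)
class UncertaintyReport:
    """The nine per-image uncertainty metric values.

    Metrics that are undefined for an image (skeletal-muscle-restricted
    metrics when the consensus mask is empty, the calibrated probability
    when no calibration model was supplied) are NaN, never silently zero.
    """

    avg_probability: float
    avg_probability_sm: float
    avg_calibrated_probability: float
    cov_pixelwise: float
    cov_sma: float
    avg_variance: float
    avg_variance_sm: float
    avg_entropy: float
    expected_entropy: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def binary_entropy(p: np.ndarray) -> np.ndarray:
    """Base-2 binary entropy with the 0·log0 := 0 convention."""
    p = np.asarray(p, dtype=np.float64)
    out = np.zeros_like(p)
    for q in (p, 1.0 - p):
        nz = q > 0
        out[nz] -= q[nz] * np.log2(q[nz])
    return out


def compute_metrics(
    ensemble: EnsemblePrediction, calibration: "CalibrationModel | None" = None
) -> UncertaintyReport:
    """Compute the nine uncertainty metrics for one ensemble prediction."""
    stack = ensemble.member_stack()  # (K, rows, cols)
    mean = ensemble.mean_map.grid
    sm = ensemble.consensus.grid.astype(bool)

    predicted_class_prob = np.maximum(mean, 1.0 - mean)
    avg_probability = float(predicted_class_prob.mean())

    avg_probability_sm = float(mean[sm].mean()) if sm.any() else math.nan

    if calibration is not None:
        cal = apply_platt(calibration, ensemble.mean_map).grid
        avg_calibrated_probability = float(np.maximum(cal, 1.0 - cal).mean())
    else:
        avg_calibrated_probability = math.nan

    var = stack.var(axis=0)  # population variance across members
    avg_variance = float(var.mean())
    avg_variance_sm = float(var[sm].mean()) if sm.any() else math.nan

    sd = np.sqrt(var)
    member_mean = stack.mean(axis=0)
    eligible = member_mean > COV_MEAN_FLOOR
    cov_pixelwise = float((sd[eligible] / member_mean[eligible]).mean()) if eligible.any() else math.nan

    areas = [m.pixel_count for m in member_masks(ensemble.members)]
    cov_sma = cov_of_areas(areas)

    avg_entropy = float(binary_entropy(mean).mean())
    expected_entropy = float(binary_entropy(stack).mean(axis=0).mean())

    return UncertaintyReport(
        avg_probability=avg_probability,
        avg_probability_sm=avg_probability_sm,
        avg_calibrated_probability=avg_calibrated_probability,
        cov_pixelwise=cov_pixelwise,
        cov_sma=cov_sma,
        avg_variance=avg_variance,
        avg_variance_sm=avg_variance_sm,
        avg_entropy=avg_entropy,
        expected_entropy=expected_entropy,
    )


def cov_of_areas(member_areas: Sequence[float]) -> float:
    """Coefficient of variation of per-member area estimates (sample SD / mean).

    Returns NaN when the mean area is zero (all members predicted nothing).
    """
    areas = np.asarray(member_areas, dtype=np.float64)
    if areas.size < 2:
        raise ValueError("need at least 2 member areas")
    mean = float(areas.mean())
    if mean == 0.0:
        return math.nan
    return float(areas.std(ddof=1) / mean)


@dataclass(frozen=True)
class CalibrationModel:
    """Platt scaling: calibrated = sigmoid(a * logit(p) + b), a >= 0."""

    a: float
    b: float
    clip_eps: float = PLATT_CLIP_EPS

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError(f"calibration slope must be non-negative for a monotone map, got {self.a}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"a": self.a, "b": self.b, "clip_eps": self.clip_eps}))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        d = json.loads(Path(path).read_text())
        return cls(a=d["a"], b=d["b"], clip_eps=d.get("clip_eps", PLATT_CLIP_EPS))


def _logit(p: np.ndarray, eps: float) -> np.ndarray:
    q = np.clip(p, eps, 1.0 - eps)
    return np.log(q / (1.0 - q))


def fit_platt(probabilities: np.ndarray, labels: np.ndarray) -> CalibrationModel:
    """Fit a logistic (Platt) recalibration of foreground probabilities.

    ``probabilities`` are raw model outputs, ``labels`` the matching binary
    reference values (flattened). A single-class label vector is rejected:
    the intercept-only direction is then non-identifiable.
    """
    from sklearn.linear_model import LogisticRegression

    p = np.asarray(probabilities, dtype=np.float64).ravel()
    y = np.asarray(labels).ravel().astype(int)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have the same length")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels contain a single class; calibration is non-identifiable")
    z = _logit(p, PLATT_CLIP_EPS).reshape(-1, 1)
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
    lr.fit(z, y)
    return CalibrationModel(a=float(lr.coef_[0, 0]), b=float(lr.intercept_[0]))


def apply_platt(model: CalibrationModel, pmap: ProbabilityMap) -> ProbabilityMap:
    """Map a probability map through a fitted calibration model."""
    z = _logit(pmap.grid, model.clip_eps)
    cal = 1.0 / (1.0 + np.exp(-(model.a * z + model.b)))
    return ProbabilityMap(grid=cal, pixel_spacing=pmap.pixel_spacing, provenance=f"{pmap.provenance}+platt")


_BANDS = (
    (0.0, 0.0, "none"),
    (0.0, 0.3, "weak"),
    (0.3, 0.5, "moderate"),
    (0.5, 0.7, "strong"),
    (0.7, 1.0, "very strong"),
)


def _band(r_abs: float) -> str:
    if math.isnan(r_abs):
        return "undefined"
    if r_abs == 1.0:
        return "perfect"
    if r_abs == 0.0:
        return "none"
    for lo, hi, name in _BANDS[1:]:
        if lo < r_abs <= hi:
            return name
    return "very strong"


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    band: str


def correlate(metric_values: Sequence[float], errors: Sequence[float]) -> CorrelationResult:
    """Pearson correlation between an uncertainty metric and SMA errors.

    The two-sided p-value comes from the exact t transform
    t = r·sqrt((n-2)/(1-r²)). The interpretation band is assigned on |r|
    (none / weak / moderate / strong / very strong / perfect); the signed r
    is reported unchanged.
    """
    x = np.asarray(metric_values, dtype=np.float64)
    y = np.asarray(errors, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(r=math.nan, p_value=math.nan, n=int(x.size), band="undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    # exactly collinear data should land in the "perfect" band even though the
    # numerical computation leaves r a few ulps shy of ±1
    if 1.0 - abs(r) < 1e-12:
        r = math.copysign(1.0, r)
    return CorrelationResult(r=r, p_value=float(res.pvalue), n=int(x.size), band=_band(abs(r)))
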