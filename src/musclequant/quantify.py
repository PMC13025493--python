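"""Physical muscle quantification: SMA, SMI, percent differences, cachexia rule.

SMA (skeletal muscle area) is the muscle pixel count converted to cm² via
the pixel spacing; SMI (skeletal muscle index) is SMA divided by squared
height in metres — the body-size-adjusted biomarker used for sarcopenia and
cachexia assessment. Percent differences against a reference measurement are
signed; cohort summaries report the mean and median of their absolute
values. The cachexia label follows the Fearon weight-loss/BMI rule:
cachectic iff >5% weight loss over six months at BMI ≥ 20, or >2% loss at
BMI < 20 (strict inequalities).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ensemble import BinaryMask

__all__ = [
    "MuscleMeasure",
    "ClinicalRecord",
    "DifferenceSummary",
    "sma_from_mask",
    "smi",
    "percent_difference",
    "summarize_differences",
    "fearon_label",
    "weight_loss_6mo",
    "longitudinal_series",
    "read_clinical_csv",
]


@dataclass(frozen=True)
class MuscleMeasure:
    """SMA measurement for one slice / time point."""

    pixel_count: int
    sma: float  # cm²
    smi: float = math.nan  # cm²/m², NaN when height unknown
    slice_index: int | None = None
    series_uid: str | None = None
    scan_date: date | None = None


@dataclass(frozen=True)
class ClinicalRecord:
    patient_id: str
    height_m: float
    weight_history: tuple[tuple[date, float], ...] = ()
    bmi: float | None = None
    sex: str | None = None
    age: float | None = None
    stage: str | None = None

    def __post_init__(self) -> None:
        if self.height_m <= 0:
            raise ValueError(f"height must be positive, got {self.height_m}")
        if self.bmi is not None and self.bmi <= 0:
            raise ValueError(f"BMI must be positive when present, got {self.bmi}")


@dataclass(frozen=True)
class DifferenceSummary:
    n: int
    mean_abs: float  # %
    median_abs: float  # %
    excluded_ids: tuple[str, ...] = ()


def sma_from_mask(mask: BinaryMask, **meta) -> MuscleMeasure:
    """Convert a muscle mask to a physical area measurement.

    cm² = pixel count × row spacing (mm) × col spacing (mm) / 100. Missing or
    non-positive spacing is an error — never a silent 1 mm assumption (the
    BinaryMask container already enforces this).
    """
    rs, cs = mask.pixel_spacing
    count = mask.pixel_count
    return MuscleMeasure(pixel_count=count, sma=count * rs * cs / 100.0, **meta)


def smi(sma_cm2: float, height_m: float) -> float:
    """Skeletal muscle index: SMA normalized by squared height (cm²/m²)."""
    if not (0.5 < height_m < 2.5):
        raise ValueError(f"non-physiological height {height_m} m")
    if sma_cm2 < 0:
        raise ValueError("SMA cannot be negative")
    return sma_cm2 / height_m**2


def percent_difference(pred_sma: float, ref_sma: float) -> float:
    """Signed percent difference of a predicted area against a reference.

    For a mask pair on one image this equals (FP − FN) / (TP + FN) × 100.
    Accepts areas or raw pixel counts (the units cancel).
    """
    if ref_sma <= 0:
        raise ValueError(f"reference area must be positive, got {ref_sma}")
    return (pred_sma - ref_sma) / ref_sma * 100.0


def summarize_differences(
    signed_diffs: Mapping[str, float], exclude_ids: Sequence[str] = ()
) -> DifferenceSummary:
    """Mean and median absolute percent difference over a cohort.

    ``signed_diffs`` maps case id → signed percent difference; ids in
    ``exclude_ids`` are dropped first (e.g., known out-of-distribution
    cases). Median of an even count is the midpoint of the central pair.
    """
    excluded = tuple(i for i in exclude_ids if i in signed_diffs)
    vals = np.array([abs(v) for k, v in signed_diffs.items() if k not in set(exclude_ids)], dtype=np.float64)
    if vals.size == 0:
        raise ValueError("no differences remain after exclusion")
    return DifferenceSummary(
        n=int(vals.size),
        mean_abs=float(vals.mean()),
        median_abs=float(np.median(vals)),
        excluded_ids=excluded,
    )


def fearon_label(weight_loss_pct_6mo: float | None, bmi: float | None) -> bool | None:
    """Cachexia label from 6-month weight loss and BMI.

    Returns None (undefined, not False) when either input is missing.
    """
    if weight_loss_pct_6mo is None or bmi is None:
        return None
    if weight_loss_pct_6mo < -100:
        raise ValueError("weight loss below -100% is impossible")
    if bmi <= 0:
        raise ValueError("BMI must be positive")
    if bmi >= 20:
        return weight_loss_pct_6mo > 5.0
    return weight_loss_pct_6mo > 2.0


def weight_loss_6mo(
    weight_history: Sequence[tuple[date, float]],
    reference_date: date,
    window_days: int = 45,
) -> float | None:
    """Percent weight loss over ~six months before ``reference_date``.

    The baseline is the history record closest to six months prior, accepted
    within ±``window_days``; the current weight is the record closest to the
    reference date (within the same tolerance). Returns None when either
    anchor is missing.
    """
    if not weight_history:
        return None
    target = reference_date - timedelta(days=182)

    def closest(anchor: date):
        rec = min(weight_history, key=lambda dw: abs((dw[0] - anchor).days))
        return rec if abs((rec[0] - anchor).days) <= window_days else None

    baseline = closest(target)
    current = closest(reference_date)
    if baseline is None or current is None or baseline[1] <= 0:
        return None
    return (baseline[1] - current[1]) / baseline[1] * 100.0


def longitudinal_series(
    measures: Sequence[MuscleMeasure], clinical: ClinicalRecord | None = None
) -> pd.DataFrame:
    """Time-ordered SMA/SMI trajectory with inter-scan deltas.

    Returns a DataFrame sorted by scan date with columns ``scan_date, sma,
    smi, pixel_count, delta_abs, delta_pct, duplicate_date``. Deltas are
    relative to the previous time point (NaN for the first). Duplicate dates
    are kept and flagged, not collapsed. When a clinical record with height
    is supplied, SMI is (re)computed from SMA.
    """
    if not measures:
        raise ValueError("need at least one measurement")
    for m in measures:
        if m.scan_date is None:
            raise ValueError("every measurement needs a scan_date")
    rows = []
    for m in sorted(measures, key=lambda m: m.scan_date):
        smi_val = m.smi
        if clinical is not None:
            smi_val = smi(m.sma, clinical.height_m)
        rows.append(
            {"scan_date": m.scan_date, "sma": m.sma, "smi": smi_val, "pixel_count": m.pixel_count}
        )
    df = pd.DataFrame(rows)
    prev = df["sma"].shift(1)
    df["delta_abs"] = df["sma"] - prev
    df["delta_pct"] = (df["sma"] - prev) / prev * 100.0
    df["duplicate_date"] = df["scan_date"].duplicated(keep=False)
    return df


CLINICAL_COLUMNS = {"patient_id", "height_m"}


def read_clinical_csv(path) -> dict[str, ClinicalRecord]:
    """Read clinical records from CSV.

    Required columns: ``patient_id, height_m``. Optional: ``bmi, sex, age,
    stage`` and a wide-or-long weight history via repeated rows with
    ``weight_date, weight`` columns.
    """
    df = pd.read_csv(path)
    missing = CLINICAL_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"clinical CSV is missing required columns: {sorted(missing)}")
    records: dict[str, ClinicalRecord] = {}
    for pid, grp in df.groupby("patient_id", sort=False):
        first = grp.iloc[0]
        history: list[tuple[date, float]] = []
        if {"weight_date", "weight"} <= set(df.columns):
            for _, row in grp.iterrows():
                if pd.notna(row["weight_date"]) and pd.notna(row["weight"]):
                    history.append((pd.Timestamp(row["weight_date"]).date(), float(row["weight"])))
        records[str(pid)] = ClinicalRecord(
            patient_id=str(pid),
            height_m=float(first["height_m"]),
            weight_history=tuple(sorted(history)),
            bmi=float(first["bmi"]) if "bmi" in grp.columns and pd.notna(first["bmi"]) else None,
            sex=str(first["sex"]) if "sex" in grp.columns and pd.notna(first["sex"]) else None,
            age=float(first["age"]) if "age" in grp.columns and pd.notna(first["age"]) else None,
            stage=str(first["stage"]) if "stage" in grp.columns and pd.notna(first["stage"]) else None,
        )
    return records
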