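"""Report files: the per-case CSV, image outputs, and longitudinal plots.

The pipeline CSV holds one row per processed slice: deidentified patient id,
scan date, series/slice identifiers, SMA/SMI, the nine uncertainty metric
values, the triage flag, and the study/series description. Undefined numeric
values (an empty consensus mask, a missing calibration model, unknown
height) are serialized as the explicit marker ``NA`` — never as 0, which
would be a valid measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .uncertainty import METRIC_NAMES

__all__ = [
    "CaseRow",
    "SCHEMA_VERSION",
    "CASE_COLUMNS",
    "write_report",
    "read_report",
    "plot_longitudinal",
    "render_uncertainty_png",
    "save_mask_png",
    "save_nifti",
    "save_probability_png",
]

SCHEMA_VERSION = "1"
NA_MARKER = "NA"

CASE_COLUMNS = (
    "schema_version",
    "patient_id",
    "scan_date",
    "series_number",
    "slice_number",
    "sma_cm2",
    "smi_cm2_m2",
    *METRIC_NAMES,
    "triage_flag",
    "description",
)


@dataclass
class CaseRow:
    patient_id: str
    scan_date: str
    series_number: str
    slice_number: int
    sma_cm2: float
    smi_cm2_m2: float
    avg_probability: float
    avg_probability_sm: float
    avg_calibrated_probability: float
    cov_pixelwise: float
    cov_sma: float
    avg_variance: float
    avg_variance_sm: float
    avg_entropy: float
    expected_entropy: float
    triage_flag: str  # "auto_accept" | "review"
    description: str = ""

    def __post_init__(self) -> None:
        if self.triage_flag not in ("auto_accept", "review"):
            raise ValueError(f"triage flag must be 'auto_accept' or 'review', got {self.triage_flag!r}")

    def __eq__(self, other) -> bool:  # NaN markers compare equal to themselves
        if not isinstance(other, CaseRow):
            return NotImplemented
        for f in fields(self):
            a, b = getattr(self, f.name), getattr(other, f.name)
            if isinstance(a, float) and isinstance(b, float):
                if math.isnan(a) and math.isnan(b):
                    continue
                if a != b:
                    return False
            elif a != b:
                return False
        return True


def write_report(rows: list[CaseRow], path: str | Path) -> None:
    """Write case rows as CSV with explicit NA markers and a schema tag."""
    records = []
    for r in rows:
        d = {"schema_version": SCHEMA_VERSION}
        d.update({f.name: getattr(r, f.name) for f in fields(r)})
        records.append(d)
    df = pd.DataFrame.from_records(records, columns=CASE_COLUMNS)
    df.to_csv(path, index=False, na_rep=NA_MARKER)


def read_report(path: str | Path) -> list[CaseRow]:
    """Read a pipeline CSV back into case rows; validates the schema."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    for col in CASE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"report is missing column {col!r}")
    extra = set(df.columns) - set(CASE_COLUMNS)
    if extra:
        raise ValueError(f"report has unknown columns {sorted(extra)!r}")
    rows = []
    float_fields = {
        "sma_cm2",
        "smi_cm2_m2",
        *METRIC_NAMES,
    }
    for _, rec in df.iterrows():
        if rec["schema_version"] != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema version {rec['schema_version']!r}")
        kwargs = {}
        for f in fields(CaseRow):
            raw = rec[f.name]
            if f.name in float_fields:
                kwargs[f.name] = math.nan if raw == NA_MARKER else float(raw)
            elif f.name == "slice_number":
                kwargs[f.name] = int(raw)
            else:
                kwargs[f.name] = raw
        rows.append(CaseRow(**kwargs))
    return rows


def plot_longitudinal(trajectory: pd.DataFrame, path: str | Path, patient_id: str = "") -> Path:
    """Plot an SMA/SMI trajectory (one figure per patient) to a PNG file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if trajectory.empty:
        raise ValueError("empty trajectory")
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(trajectory["scan_date"], trajectory["sma"], "o-", label="SMA (cm²)")
    if trajectory["smi"].notna().any():
        ax2 = ax.twinx()
        ax2.plot(trajectory["scan_date"], trajectory["smi"], "s--", color="tab:orange", label="SMI (cm²/m²)")
        ax2.set_ylabel("SMI (cm²/m²)")
    ax.set_xlabel("scan date")
    ax.set_ylabel("SMA (cm²)")
    ax.set_title(f"Longitudinal muscle measurements {patient_id}".strip())
    fig.autofmt_xdate()
    path = Path(path)
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
    return path


def render_uncertainty_png(variance_grid: np.ndarray, path: str | Path, vmax: float | None = None) -> Path:
    """Render a pixel-wise uncertainty map on a black→red→yellow→white heat scale."""
    import matplotlib

    matplotlib.use("Agg")
    from matplotlib import cm
    from PIL import Image

    v = np.asarray(variance_grid, dtype=np.float64)
    top = vmax if vmax is not None else (float(v.max()) or 1.0)
    scaled = np.clip(v / top, 0.0, 1.0)
    rgba = (cm.hot(scaled) * 255).astype(np.uint8)
    path = Path(path)
    Image.fromarray(rgba[..., :3]).save(path)
    return path


def save_mask_png(mask_grid: np.ndarray, path: str | Path) -> Path:
    """Save a {0,1} mask as a {0,255} 8-bit PNG."""
    from PIL import Image

    path = Path(path)
    Image.fromarray((np.asarray(mask_grid) > 0).astype(np.uint8) * 255).save(path)
    return path


def save_probability_png(grid: np.ndarray, path: str | Path) -> Path:
    """Save a probability map as 8-bit PNG (quantized — lossy; NIfTI is exact)."""
    from PIL import Image

    path = Path(path)
    Image.fromarray(np.round(np.clip(grid, 0, 1) * 255).astype(np.uint8)).save(path)
    return path


def save_nifti(grid: np.ndarray, path: str | Path, pixel_spacing: tuple[float, float] = (1.0, 1.0)) -> Path:
    """Save a 2-D grid as NIfTI (exact interchange format)."""
    import nibabel as nib

    affine = np.diag([pixel_spacing[0], pixel_spacing[1], 1.0, 1.0])
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(grid)[..., None].astype(np.float64), affine), str(path))
    return path
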