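"""DICOM series selection and L3-level slice identification.

Axial series are identified from the ``ImageOrientationPatient`` direction
cosines; slices are grouped by the acquisition-identity attributes (study,
series, frame of reference, acquisition number, slice thickness, spacing
between slices) and sorted by patient-z. The L3 level comes from an external
vertebra-label volume (NIfTI, produced by any anatomical segmentation
backend) in which the L3 vertebra carries label 29; the slice fed to the
segmentation model is the floor midpoint of the longest contiguous L3 run
("mid-L3") or its last slice ("end-L3").

Re-implementing the anatomical labeling backend is out of scope: it is a
pluggable file-based interface.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "SliceHeader",
    "SeriesGroup",
    "VertebraLabelVolume",
    "L3NotFoundError",
    "is_axial",
    "group_and_sort",
    "hu_convert",
    "l3_slice_range",
    "mid_slice",
    "filter_groups_by_description",
    "header_from_dataset",
    "load_label_volume",
    "hu_window_to_uint8",
    "write_selection_manifest",
]

L3_LABEL = 29
#: |normal · ẑ| above this counts as axial: admits mild gantry tilt,
#: excludes sagittal/coronal planes.
AXIAL_NORMAL_TOLERANCE = 0.9
_UNIT_TOL = 1e-3


class L3NotFoundError(ValueError):
    """The vertebra-label volume contains no L3 voxels (scan misses L3)."""


@dataclass(frozen=True)
class SliceHeader:
    """The DICOM header attributes this pipeline needs from one slice."""

    study_uid: str
    series_uid: str
    frame_of_reference_uid: str
    orientation: tuple[float, ...]  # 6 direction cosines, row then column
    position: tuple[float, float, float]  # mm, patient coordinates
    pixel_spacing: tuple[float, float]  # (row, col) mm
    slice_thickness: float
    acquisition_number: int | None = None
    spacing_between_slices: float | None = None
    rescale_slope: float | None = 1.0
    rescale_intercept: float | None = 0.0
    series_description: str = ""
    study_description: str = ""
    source_path: str | None = None

    def __post_init__(self) -> None:
        _validate_orientation(self.orientation)

    @property
    def patient_z(self) -> float:
        return self.position[2]

    def group_key(self) -> tuple:
        return (
            self.study_uid,
            self.series_uid,
            self.frame_of_reference_uid,
            self.acquisition_number,
            self.slice_thickness,
            self.spacing_between_slices,
        )


def _validate_orientation(orientation: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(orientation, dtype=np.float64)
    if o.shape != (6,):
        raise ValueError(f"orientation must hold 6 direction cosines, got {len(o)}")
    row, col = o[:3], o[3:]
    if abs(np.linalg.norm(row) - 1) > _UNIT_TOL or abs(np.linalg.norm(col) - 1) > _UNIT_TOL:
        raise ValueError(f"direction cosines must be unit vectors: {orientation}")
    if abs(float(row @ col)) > _UNIT_TOL:
        raise ValueError(f"row and column cosines must be orthogonal: {orientation}")
    return row, col


@dataclass(frozen=True)
class SeriesGroup:
    """Slices sharing one acquisition identity, ordered by patient-z."""

    key: tuple
    slices: tuple[SliceHeader, ...]
    duplicate_positions: tuple[float, ...] = field(default=())

    @property
    def series_description(self) -> str:
        return self.slices[0].series_description if self.slices else ""


def is_axial(orientation: Sequence[float]) -> bool:
    """True iff the slice normal is within ~26° of the patient z-axis.

    The normal is the cross product of the row and column cosines; axial
    means |normal_z| > 0.9, which is invariant to in-plane rotation.
    """
    row, col = _validate_orientation(orientation)
    normal = np.cross(row, col)
    return abs(float(normal[2])) > AXIAL_NORMAL_TOLERANCE


def group_and_sort(headers: Sequence[SliceHeader]) -> list[SeriesGroup]:
    """Partition headers into acquisition groups and sort each by patient-z.

    Every header lands in exactly one group. Duplicate (group, position)
    pairs are kept and reported on the group, never silently dropped.
    Group order follows first appearance in the input, so the operation is
    deterministic and idempotent.
    """
    if not headers:
        raise ValueError("no headers to group")
    buckets: dict[tuple, list[SliceHeader]] = {}
    order: list[tuple] = []
    for h in headers:
        k = h.group_key()
        if k not in buckets:
            buckets[k] = []
            order.append(k)
        buckets[k].append(h)
    groups = []
    for k in order:
        slices = sorted(buckets[k], key=lambda h: h.patient_z)
        zs = [h.patient_z for h in slices]
        dups = tuple(sorted({z for z in zs if zs.count(z) > 1}))
        groups.append(SeriesGroup(key=k, slices=tuple(slices), duplicate_positions=dups))
    return groups


def hu_convert(raw_pixel, slope: float | None, intercept: float | None, context: str = ""):
    """Apply the DICOM rescale to raw pixel values: HU = slope·raw + intercept."""
    where = f" ({context})" if context else ""
    if slope is None or intercept is None:
        raise ValueError(f"missing rescale slope/intercept{where}")
    if slope == 0:
        raise ValueError(f"rescale slope must be non-zero{where}")
    return np.asarray(raw_pixel, dtype=np.float64) * slope + intercept


@dataclass(frozen=True)
class VertebraLabelVolume:
    """Anatomical label volume aligned to a series group, axis 0 = slices."""

    labels: np.ndarray  # (n_slices, rows, cols) integer labels
    label_map: dict = field(default_factory=lambda: {L3_LABEL: "L3"})

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"label volume must be 3-D (slices, rows, cols), got {labels.shape}")
        object.__setattr__(self, "labels", labels)

    def check_alignment(self, group: SeriesGroup) -> None:
        if self.labels.shape[0] != len(group.slices):
            raise ValueError(
                f"label volume has {self.labels.shape[0]} slices but group has {len(group.slices)}"
            )


def l3_slice_range(volume: VertebraLabelVolume, l3_label: int = L3_LABEL) -> tuple[int, int]:
    """Longest contiguous run of slice indices containing the L3 label.

    Ties between equally long fragmented runs break toward the inferior run
    (lower slice index under ascending patient-z ordering). Raises
    L3NotFoundError when the label is absent — the scan does not cover L3.
    """
    present = np.array([(sl == l3_label).any() for sl in volume.labels])
    if not present.any():
        raise L3NotFoundError(f"L3 not found: no voxel carries label {l3_label}")
    runs: list[tuple[int, int]] = []
    start = None
    for i, p in enumerate(present):
        if p and start is None:
            start = i
        elif not p and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(present) - 1))
    best_len = max(e - s for s, e in runs)
    return next((s, e) for s, e in runs if e - s == best_len)


def mid_slice(run: tuple[int, int], mode: Literal["mid", "end"] = "mid") -> int:
    """Representative slice of an L3 run: floor midpoint, or the last slice."""
    first, last = run
    if last < first:
        raise ValueError(f"empty slice run {run}")
    if mode == "mid":
        return (first + last) // 2
    if mode == "end":
        return last
    raise ValueError(f"unknown L3 mode {mode!r}; expected 'mid' or 'end'")


def filter_groups_by_description(
    groups: Iterable[SeriesGroup],
    include_keywords: Sequence[str] = (),
    exclude_keywords: Sequence[str] = (),
) -> list[SeriesGroup]:
    """Keyword filter on series/study description (case-insensitive substrings).

    Used to prefer e.g. venous-phase or non-contrast axial series. With no
    include keywords every group passes the include stage.
    """
    out = []
    for g in groups:
        text = " ".join(
            (s.series_description + " " + s.study_description) for s in g.slices[:1]
        ).lower()
        if include_keywords and not any(k.lower() in text for k in include_keywords):
            continue
        if any(k.lower() in text for k in exclude_keywords):
            continue
        out.append(g)
    return out


def header_from_dataset(ds, source_path: str | None = None) -> SliceHeader:
    """Build a SliceHeader from a pydicom dataset (headers only, no pixels)."""

    def get(tag, default=None):
        v = getattr(ds, tag, default)
        return default if v in (None, "") else v

    acq = get("AcquisitionNumber")
    return SliceHeader(
        study_uid=str(get("StudyInstanceUID", "")),
        series_uid=str(get("SeriesInstanceUID", "")),
        frame_of_reference_uid=str(get("FrameOfReferenceUID", "")),
        orientation=tuple(float(x) for x in ds.ImageOrientationPatient),
        position=tuple(float(x) for x in ds.ImagePositionPatient),
        pixel_spacing=tuple(float(x) for x in ds.PixelSpacing),
        slice_thickness=float(get("SliceThickness", math.nan)),
        acquisition_number=int(acq) if acq is not None else None,
        spacing_between_slices=(
            float(get("SpacingBetweenSlices")) if get("SpacingBetweenSlices") is not None else None
        ),
        rescale_slope=float(get("RescaleSlope")) if get("RescaleSlope") is not None else None,
        rescale_intercept=float(get("RescaleIntercept")) if get("RescaleIntercept") is not None else None,
        series_description=str(get("SeriesDescription", "")),
        study_description=str(get("StudyDescription", "")),
        source_path=source_path,
    )


def load_label_volume(path, slice_axis: int = 2) -> VertebraLabelVolume:
    """Load an anatomical label volume from NIfTI; move the slice axis first."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(np.int32)
    data = np.moveaxis(data, slice_axis, 0)
    return VertebraLabelVolume(labels=data)


def hu_window_to_uint8(hu: np.ndarray, center: float = 40.0, width: float = 400.0) -> np.ndarray:
    """Window an HU image to 8-bit for PNG export (default: soft-tissue window)."""
    lo, hi = center - width / 2.0, center + width / 2.0
    scaled = (np.clip(hu, lo, hi) - lo) / (hi - lo)
    return np.round(scaled * 255).astype(np.uint8)


def write_selection_manifest(
    path,
    group: SeriesGroup,
    slice_index: int,
    l3_run: tuple[int, int],
    mode: str,
    extra: dict | None = None,
) -> None:
    """Record which series/slice was chosen and why (auditable provenance)."""
    chosen = group.slices[slice_index]
    manifest = {
        "group_key": list(map(lambda x: x if x is None else str(x), group.key)),
        "n_slices": len(group.slices),
        "duplicate_positions": list(group.duplicate_positions),
        "l3_run": list(l3_run),
        "l3_mode": mode,
        "slice_index": slice_index,
        "patient_z": chosen.patient_z,
        "series_description": chosen.series_description,
        "source_path": chosen.source_path,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2))
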