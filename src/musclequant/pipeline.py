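"""End-to-end orchestration: inputs → consensus masks → metrics → triage → report.

The pipeline consumes either a synthetic phantom cohort (fully
self-contained, used for testing and demonstration) or pre-computed member
probability maps written by an external segmentation backend (one directory
per case holding ``member_*.nii`` files and optionally a ``reference.nii``
mask). For every case it aggregates the ensemble, measures SMA, computes the
nine uncertainty metrics, assigns a triage flag, and writes the report
directory: the case CSV, consensus masks (PNG + NIfTI), uncertainty heat
maps, a review manifest of flagged cases, and — when references exist —
triage operating points.

A failing case is logged and skipped; the remaining cases still run. The
result distinguishes a clean run from a partial one.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import phantom as ph
from .agreement import agreement_report
from .ensemble import BinaryMask, ProbabilityMap, aggregate
from .quantify import sma_from_mask, smi
from .reporting import (
    CaseRow,
    render_uncertainty_png,
    save_mask_png,
    save_nifti,
    write_report,
)
from .triage import TriageConfig, evaluate, operating_curve, quantile_threshold, select_threshold
from .uncertainty import CalibrationModel, compute_metrics

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("musclequant.pipeline")


@dataclass(frozen=True)
class PhantomCohortConfig:
    n_cases: int = 10
    n_corrupt: int = 3
    severity: float = 0.8
    corruption_mode: str = "streak_artifact"
    grid_shape: tuple[int, int] = (256, 256)
    sim: ph.EnsembleSimConfig = field(default_factory=ph.EnsembleSimConfig)


@dataclass(frozen=True)
class PipelineConfig:
    output_dir: str
    input_dir: str | None = None  # directory of per-case member-map folders
    phantom_cohort: PhantomCohortConfig | None = None
    l3_mode: str = "mid"
    uncertainty_metric: str = "avg_variance"  # metric driving the triage flag
    triage: TriageConfig = field(default_factory=lambda: TriageConfig(policy="quantile", policy_parameter=0.75))
    calibration_path: str | None = None
    height_m: float | None = None  # single-height cohorts (phantom demos)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.l3_mode not in ("mid", "end"):
            raise ValueError(f"l3_mode must be 'mid' or 'end', got {self.l3_mode!r}")
        if (self.input_dir is None) == (self.phantom_cohort is None):
            raise ValueError("exactly one of input_dir or phantom_cohort must be set")


@dataclass
class PipelineResult:
    output_dir: Path
    report_path: Path
    n_cases: int
    n_failed: int
    threshold: float

    @property
    def clean(self) -> bool:
        return self.n_failed == 0


@dataclass
class _Case:
    case_id: str
    members: list[ProbabilityMap]
    reference: BinaryMask | None
    description: str


def _load_cases_from_dir(input_dir: Path) -> list[_Case]:
    import nibabel as nib

    def read2d(p: Path) -> np.ndarray:
        arr = np.asarray(nib.load(str(p)).dataobj, dtype=np.float64)
        return np.squeeze(arr)

    case_dirs = sorted(d for d in input_dir.iterdir() if d.is_dir())
    if not case_dirs:
        raise ValueError(f"no case directories under {input_dir}")
    cases = []
    for d in case_dirs:
        member_files = sorted(d.glob("member_*.nii*"))
        if not member_files:
            raise ValueError(f"case {d.name} has no member_*.nii probability maps")
        meta = {}
        meta_path = d / "case.json"
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
        spacing = tuple(meta.get("pixel_spacing", (1.0, 1.0)))
        members = [
            ProbabilityMap(grid=np.clip(read2d(f), 0.0, 1.0), pixel_spacing=spacing, provenance=f.stem)
            for f in member_files
        ]
        ref = None
        ref_files = sorted(d.glob("reference.nii*"))
        if ref_files:
            ref = BinaryMask(grid=(read2d(ref_files[0]) > 0.5).astype(np.uint8), pixel_spacing=spacing)
        cases.append(_Case(case_id=d.name, members=members, reference=ref, description=meta.get("description", "")))
    return cases


def _phantom_cases(cfg: PhantomCohortConfig, seed: int) -> list[_Case]:
    cohort = ph.generate_cohort(
        n_cases=cfg.n_cases,
        n_corrupt=cfg.n_corrupt,
        seed=seed,
        severity=cfg.severity,
        corruption_mode=cfg.corruption_mode,
        sim=cfg.sim,
        grid_shape=cfg.grid_shape,
    )
    return [
        _Case(
            case_id=c.case_id,
            members=list(c.members),
            reference=c.reference,
            description="synthetic phantom" + (" (corrupted)" if c.corrupted else ""),
        )
        for c in cohort
    ]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full pipeline and write the report directory."""
    out = Path(config.output_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    (out / "uncertainty").mkdir(exist_ok=True)

    log.info(
        "pipeline start: l3_mode=%s triage_metric=%s policy=%s(param=%s) error_cutoff=%s seed=%d "
        "consensus=strict mean>0.5, entropies base-2, pixel variance population-n, area CoV sample-(n-1)",
        config.l3_mode,
        config.uncertainty_metric,
        config.triage.policy,
        config.triage.policy_parameter,
        config.triage.error_cutoff,
        config.seed,
    )

    if config.phantom_cohort is not None:
        cases = _phantom_cases(config.phantom_cohort, config.seed)
    else:
        cases = _load_cases_from_dir(Path(config.input_dir))

    calibration = CalibrationModel.from_json(config.calibration_path) if config.calibration_path else None

    processed = []
    n_failed = 0
    for case in cases:
        try:
            pred = aggregate(case.members)
            report = compute_metrics(pred, calibration=calibration)
            measure = sma_from_mask(pred.consensus)
            err = None
            agr = None
            if case.reference is not None:
                agr = agreement_report(pred.consensus, case.reference)
                err = agr.signed_diff
            processed.append((case, pred, report, measure, err, agr))
        except Exception:  # noqa: BLE001 — a bad case must not sink the cohort
            log.exception("case %s failed; skipping", case.case_id)
            n_failed += 1
    if not processed:
        raise ValueError("no case processed successfully")

    metric_values = [getattr(rep, config.uncertainty_metric) for _, _, rep, _, _, _ in processed]
    if any(math.isnan(v) for v in metric_values):
        raise ValueError(f"triage metric {config.uncertainty_metric} undefined for some case")

    errors = [e for *_, e, _ in processed]
    have_refs = all(e is not None for e in errors)
    if config.triage.policy == "quantile":
        threshold = quantile_threshold(metric_values, config.triage.policy_parameter)
    else:
        if not have_refs:
            raise ValueError("validation-based triage policies need reference masks")
        curve = operating_curve(metric_values, [abs(e) for e in errors], sorted(set(metric_values)), config.triage.error_cutoff)
        threshold = select_threshold(curve, config.triage)

    rows: list[CaseRow] = []
    flagged_manifest = []
    for (case, pred, rep, measure, err, agr), u in zip(processed, metric_values):
        flag = "review" if u > threshold else "auto_accept"
        mask_png = save_mask_png(pred.consensus.grid, out / "masks" / f"{case.case_id}.png")
        save_nifti(pred.consensus.grid, out / "masks" / f"{case.case_id}.nii", pred.consensus.pixel_spacing)
        var_map = pred.member_stack().var(axis=0)
        render_uncertainty_png(var_map, out / "uncertainty" / f"{case.case_id}.png")
        smi_val = smi(measure.sma, config.height_m) if config.height_m else math.nan
        d = rep.as_dict()
        rows.append(
            CaseRow(
                patient_id=case.case_id,
                scan_date="",
                series_number="",
                slice_number=0,
                sma_cm2=measure.sma,
                smi_cm2_m2=smi_val,
                triage_flag=flag,
                description=case.description,
                **d,
            )
        )
        if flag == "review":
            flagged_manifest.append(
                {
                    "case_id": case.case_id,
                    "uncertainty_metric": config.uncertainty_metric,
                    "uncertainty_value": u,
                    "mask_path": str(mask_png.relative_to(out)),
                }
            )

    report_path = out / "cases.csv"
    write_report(rows, report_path)
    (out / "review_manifest.json").write_text(
        json.dumps({"threshold": threshold, "metric": config.uncertainty_metric, "flagged": flagged_manifest}, indent=2)
    )
    if have_refs:
        import pandas as pd

        curve = operating_curve(metric_values, [abs(e) for e in errors], sorted(set(metric_values)), config.triage.error_cutoff)
        pd.DataFrame([dataclasses.asdict(p) for p in curve]).to_csv(out / "operating_points.csv", index=False, na_rep="NA")
        op = evaluate(metric_values, [abs(e) for e in errors], threshold, config.triage.error_cutoff)
        summary = {
            k: (None if isinstance(v, float) and math.isnan(v) else v)
            for k, v in dataclasses.asdict(op).items()
        }  # NaN is not valid JSON; undefined rates become null
        (out / "triage_summary.json").write_text(json.dumps(summary, indent=2))

    log.info("pipeline done: %d cases, %d failed, threshold=%.6g", len(rows), n_failed, threshold)
    return PipelineResult(
        output_dir=out, report_path=report_path, n_cases=len(rows), n_failed=n_failed, threshold=threshold
    )
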