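"""Synthetic L3-like CT phantoms, simulated ensembles, and corruptions.

Patient CTs and trained segmentation weights are not shippable, so every
downstream stage (aggregation, uncertainty metrics, quantification, triage)
is exercised against parametric phantoms: an elliptical body outline filled
with fat-density tissue, five muscle compartments mimicking the L3-level
topology (two paraspinal and two psoas ellipses plus an abdominal-wall
annulus sector), and a vertebral-body disc of bone.

Simulated ensemble members are built from the reference mask via three
separable knobs:

* ``boundary_sigma`` — Gaussian blur of the indicator, a soft probability
  ramp at the muscle boundary shared by all members (aleatoric-like);
* ``member_jitter`` — a smooth random boundary displacement applied per
  member (epistemic: members disagree where the boundary is);
* ``label_noise`` — random isolated probability flips (aleatoric analogue).

Corruptions emulate noisy / out-of-distribution scans: they co-elevate
segmentation error and ensemble disagreement, which is the behaviour the
uncertainty-based triage is designed to detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .ensemble import BinaryMask, ProbabilityMap

__all__ = [
    "MuscleComponent",
    "PhantomSpec",
    "EnsembleSimConfig",
    "CorruptionSpec",
    "PhantomGeometryError",
    "make_phantom",
    "simulate_ensemble",
    "mask_pair_with_counts",
    "corrupt",
    "default_spec",
    "PhantomCase",
    "generate_cohort",
]


class PhantomGeometryError(ValueError):
    """Raised when requested muscle components do not fit the body outline."""


@dataclass(frozen=True)
class MuscleComponent:
    """One parametric muscle compartment.

    ``kind`` is ``"ellipse"`` (center, target area, row/col aspect ratio) or
    ``"annulus_sector"`` (center, outer radius, angular span; the inner
    radius is solved from the target area). ``target_area_px`` is the pixel
    count the rasterized shape should cover.
    """

    kind: Literal["ellipse", "annulus_sector"]
    center: tuple[float, float]  # (row, col), pixels
    target_area_px: float
    aspect: float = 1.0  # ellipse: semi-axis_row / semi-axis_col
    r_outer: float = 0.0  # annulus sector only
    theta_range: tuple[float, float] = (0.0, 2 * math.pi)  # radians, annulus sector

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        rows, cols = shape
        rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
        dr, dc = rr - self.center[0], cc - self.center[1]
        if self.kind == "ellipse":
            if self.aspect <= 0 or self.target_area_px <= 0:
                raise PhantomGeometryError(f"invalid ellipse parameters: {self}")
            a_col = math.sqrt(self.target_area_px / (math.pi * self.aspect))
            a_row = self.aspect * a_col
            return (dr / a_row) ** 2 + (dc / a_col) ** 2 <= 1.0
        if self.kind == "annulus_sector":
            span = self.theta_range[1] - self.theta_range[0]
            if self.r_outer <= 0 or span <= 0:
                raise PhantomGeometryError(f"invalid annulus sector parameters: {self}")
            r_in_sq = self.r_outer**2 - 2.0 * self.target_area_px / span
            if r_in_sq < 0:
                raise PhantomGeometryError(
                    f"annulus sector target area {self.target_area_px} exceeds the "
                    f"disc of radius {self.r_outer}"
                )
            rad = np.hypot(dr, dc)
            # angle measured from the anterior direction (negative row axis)
            theta = np.arctan2(dc, -dr)
            return (
                (rad <= self.r_outer)
                & (rad >= math.sqrt(r_in_sq))
                & (theta >= self.theta_range[0])
                & (theta <= self.theta_range[1])
            )
        raise PhantomGeometryError(f"unknown component kind {self.kind!r}")


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int] = (256, 256)
    pixel_spacing: tuple[float, float] = (1.5, 1.5)  # mm
    body_axes: tuple[float, float] = (88.0, 112.0)  # semi-axes (row, col), pixels
    muscle_components: tuple[MuscleComponent, ...] = ()
    hu_levels: dict = field(
        default_factory=lambda: {"background": -1000.0, "fat": -80.0, "muscle": 40.0, "bone": 700.0}
    )
    hu_noise_sd: float = 12.0
    bone_radius: float = 14.0  # vertebral body disc, pixels; 0 disables
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_shape[0] < 64 or self.grid_shape[1] < 64:
            raise ValueError(f"grid must be at least 64x64, got {self.grid_shape}")
        if min(self.body_axes) <= 0 or min(self.pixel_spacing) <= 0:
            raise ValueError("body axes and pixel spacing must be positive")


def default_spec(
    seed: int = 0, total_muscle_px: float | None = None, grid_shape: tuple[int, int] = (256, 256)
) -> PhantomSpec:
    """A realistic default phantom: ~5,800 muscle pixels at 1.5 mm spacing on
    the 256×256 grid (≈130 cm² SMA, a typical adult L3 value), five
    compartments. When ``total_muscle_px`` is omitted it scales with the grid
    area so the compartments fit the scaled body outline.
    """
    rows, cols = grid_shape
    cr, cc = rows / 2.0, cols / 2.0
    scale_r = rows / 256.0
    scale_c = cols / 256.0
    a = total_muscle_px if total_muscle_px is not None else 5800.0 * scale_r * scale_c
    components = (
        # paraspinal (erector spinae) pair, posterior
        MuscleComponent("ellipse", (cr + 52 * scale_r, cc - 30 * scale_c), 0.21 * a, aspect=0.8),
        MuscleComponent("ellipse", (cr + 52 * scale_r, cc + 30 * scale_c), 0.21 * a, aspect=0.8),
        # psoas pair, flanking the vertebra
        MuscleComponent("ellipse", (cr + 14 * scale_r, cc - 26 * scale_c), 0.13 * a, aspect=1.3),
        MuscleComponent("ellipse", (cr + 14 * scale_r, cc + 26 * scale_c), 0.13 * a, aspect=1.3),
        # abdominal wall, anterior annulus sector
        MuscleComponent(
            "annulus_sector",
            (cr, cc),
            0.32 * a,
            r_outer=80.0 * min(scale_r, scale_c),
            theta_range=(-2.0, 2.0),
        ),
    )
    return PhantomSpec(
        grid_shape=grid_shape,
        body_axes=(88.0 * scale_r, 112.0 * scale_c),
        muscle_components=components,
        seed=seed,
    )


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, BinaryMask]:
    """Render the HU image and reference muscle mask for a phantom spec.

    The mask pixel count is guaranteed within 5% of the summed component
    target areas; overlapping components or components escaping the body
    outline are rejected with a diagnostic. Identical spec (including seed)
    reproduces bit-identical outputs.
    """
    rows, cols = spec.grid_shape
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    cr, ccol = rows / 2.0, cols / 2.0
    body = ((rr - cr) / spec.body_axes[0]) ** 2 + ((cc - ccol) / spec.body_axes[1]) ** 2 <= 1.0

    mask = np.zeros(spec.grid_shape, dtype=bool)
    target_total = 0.0
    for i, comp in enumerate(spec.muscle_components):
        shape_mask = comp.rasterize(spec.grid_shape)
        outside = shape_mask & ~body
        if outside.any():
            raise PhantomGeometryError(
                f"muscle component {i} ({comp.kind}) extends {int(outside.sum())} "
                "pixels beyond the body outline"
            )
        mask |= shape_mask
        target_total += comp.target_area_px

    if target_total > 0:
        count = int(mask.sum())
        if abs(count - target_total) > 0.05 * target_total:
            raise PhantomGeometryError(
                f"rendered muscle pixel count {count} deviates more than 5% from the "
                f"summed target {target_total:.0f} (components overlap or are clipped)"
            )

    hu = np.full(spec.grid_shape, spec.hu_levels["background"], dtype=np.float64)
    hu[body] = spec.hu_levels["fat"]
    hu[mask] = spec.hu_levels["muscle"]
    if spec.bone_radius > 0:
        bone = np.hypot(rr - (cr + 30 * rows / 256.0), cc - ccol) <= spec.bone_radius
        hu[bone & body] = spec.hu_levels["bone"]
    if spec.hu_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.hu_noise_sd, size=spec.grid_shape)
    return hu, BinaryMask(grid=mask.astype(np.uint8), pixel_spacing=spec.pixel_spacing)


@dataclass(frozen=True)
class EnsembleSimConfig:
    n_members: int = 10
    boundary_sigma: float = 1.5  # pixels
    member_jitter: float = 0.8  # pixels (RMS boundary displacement per member)
    label_noise: float = 0.0  # per-pixel flip probability
    jitter_smoothness: float = 8.0  # correlation length of the displacement field
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 2:
            raise ValueError("n_members must be at least 2 (variance across members undefined)")
        if self.boundary_sigma < 0 or self.member_jitter < 0:
            raise ValueError("boundary_sigma and member_jitter must be non-negative")
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must lie in [0, 0.5)")


def simulate_ensemble(reference_mask: BinaryMask, cfg: EnsembleSimConfig) -> list[ProbabilityMap]:
    """Simulate K member probability maps around a reference mask.

    With all knobs at zero every member equals the mask indicator exactly.
    """
    if reference_mask.pixel_count == 0:
        raise ValueError("reference mask is empty; cannot simulate a segmentation ensemble")
    base = reference_mask.grid.astype(np.float64)
    if cfg.boundary_sigma > 0:
        base = ndimage.gaussian_filter(base, sigma=cfg.boundary_sigma)
        base = np.clip(base, 0.0, 1.0)

    rng = np.random.default_rng(cfg.seed)
    rows, cols = base.shape
    grid_r, grid_c = np.mgrid[0:rows, 0:cols].astype(np.float64)
    members: list[ProbabilityMap] = []
    for k in range(cfg.n_members):
        grid = base
        if cfg.member_jitter > 0:
            grid = _warp(base, grid_r, grid_c, rng, cfg.member_jitter, cfg.jitter_smoothness)
        if cfg.label_noise > 0:
            flips = rng.random(base.shape) < cfg.label_noise
            grid = np.where(flips, 1.0 - grid, grid)
        members.append(
            ProbabilityMap(
                grid=np.clip(grid, 0.0, 1.0),
                pixel_spacing=reference_mask.pixel_spacing,
                provenance=f"sim-{k}",
            )
        )
    return members


def _warp(
    base: np.ndarray,
    grid_r: np.ndarray,
    grid_c: np.ndarray,
    rng: np.random.Generator,
    jitter: float,
    smoothness: float,
) -> np.ndarray:
    """Displace the probability field by a smooth random field of RMS ``jitter``."""
    disp = []
    for _ in range(2):
        f = ndimage.gaussian_filter(rng.standard_normal(base.shape), sigma=smoothness)
        rms = float(np.sqrt(np.mean(f**2)))
        disp.append(f / rms * jitter if rms > 0 else f)
    return ndimage.map_coordinates(base, [grid_r + disp[0], grid_c + disp[1]], order=1, mode="nearest")


def mask_pair_with_counts(
    tp: int, fp: int, fn: int, grid_shape: tuple[int, int], pixel_spacing: tuple[float, float] = (1.0, 1.0)
) -> tuple[BinaryMask, BinaryMask]:
    """Build a (prediction, reference) mask pair with exact confusion counts.

    Pixels are packed row-major into three disjoint blocks (TP, FP, FN); the
    geometry is irrelevant to count-based agreement metrics.
    """
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    size = grid_shape[0] * grid_shape[1]
    if tp + fp + fn > size:
        raise ValueError(f"tp+fp+fn = {tp + fp + fn} exceeds grid capacity {size}")
    pred = np.zeros(size, dtype=np.uint8)
    ref = np.zeros(size, dtype=np.uint8)
    pred[0 : tp + fp] = 1
    ref[0:tp] = 1
    ref[tp + fp : tp + fp + fn] = 1
    return (
        BinaryMask(grid=pred.reshape(grid_shape), pixel_spacing=pixel_spacing),
        BinaryMask(grid=ref.reshape(grid_shape), pixel_spacing=pixel_spacing),
    )


_MODES = ("streak_artifact", "field_truncation", "blur", "intensity_shift")


@dataclass(frozen=True)
class CorruptionSpec:
    mode: Literal["streak_artifact", "field_truncation", "blur", "intensity_shift"]
    severity: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown corruption mode {self.mode!r}; expected one of {_MODES}")
        if not (0.0 <= self.severity <= 1.0):
            raise ValueError(f"severity must lie in [0, 1], got {self.severity}")


def corrupt(data, spec: CorruptionSpec):
    """Apply a deterministic corruption to an HU image or ensemble member list.

    ``severity=0`` is the identity. On member probability maps the streak
    artifact injects member-specific perturbations (disagreement rises) plus
    a shared bias (the consensus, and hence the measured area, shifts) —
    mimicking how real artifacts degrade accuracy and inflate uncertainty
    together.
    """
    if spec.severity == 0.0:
        return data
    if isinstance(data, np.ndarray):
        return _corrupt_hu(data, spec)
    if isinstance(data, (list, tuple)) and all(isinstance(m, ProbabilityMap) for m in data):
        return _corrupt_members(list(data), spec)
    raise TypeError("corrupt() expects an HU ndarray or a list of ProbabilityMap")


def _streak_band(shape: tuple[int, int], rng: np.random.Generator, n_lines: int, width: float) -> np.ndarray:
    """Gaussian-profiled band along random lines through the image centre region."""
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols].astype(np.float64)
    band = np.zeros(shape)
    for _ in range(n_lines):
        theta = rng.uniform(0, math.pi)
        # line passes near the centre with a random perpendicular offset
        offset = rng.uniform(-0.25, 0.25) * min(rows, cols)
        d = (rr - rows / 2) * math.cos(theta) + (cc - cols / 2) * math.sin(theta) - offset
        band = np.maximum(band, np.exp(-0.5 * (d / width) ** 2))
    return band


def _corrupt_hu(hu: np.ndarray, spec: CorruptionSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    s = spec.severity
    if spec.mode == "streak_artifact":
        band = _streak_band(hu.shape, rng, n_lines=1 + int(s * 5), width=4.0)
        signs = rng.choice([-1.0, 1.0])
        return hu + signs * s * 800.0 * band
    if spec.mode == "field_truncation":
        out = hu.copy()
        cut = int(round(s * 0.25 * hu.shape[1]))
        if cut > 0:
            out[:, :cut] = -1000.0
        return out
    if spec.mode == "blur":
        return ndimage.gaussian_filter(hu, sigma=4.0 * s)
    if spec.mode == "intensity_shift":
        return hu + 200.0 * s
    raise AssertionError("unreachable")


def _logit(p: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    q = np.clip(p, eps, 1.0 - eps)
    return np.log(q / (1.0 - q))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _corrupt_members(members: list[ProbabilityMap], spec: CorruptionSpec) -> list[ProbabilityMap]:
    rng = np.random.default_rng(spec.seed)
    s = spec.severity
    shape = members[0].grid.shape
    out: list[ProbabilityMap] = []
    if spec.mode == "streak_artifact":
        band = _streak_band(shape, rng, n_lines=1 + int(s * 4), width=8.0)
        shared = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=6.0)
        shared = shared / max(float(np.sqrt(np.mean(shared**2))), 1e-12) * 3.0 * s
        for m in members:
            noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=4.0)
            noise = noise / max(float(np.sqrt(np.mean(noise**2))), 1e-12) * 4.0 * s
            z = _logit(m.grid) + band * (shared + noise)
            out.append(ProbabilityMap(grid=_sigmoid(z), pixel_spacing=m.pixel_spacing, provenance=m.provenance))
        return out
    if spec.mode == "field_truncation":
        cut = int(round(s * 0.25 * shape[1]))
        for m in members:
            g = m.grid.copy()
            if cut > 0:
                g[:, :cut] = 0.0
            out.append(ProbabilityMap(grid=g, pixel_spacing=m.pixel_spacing, provenance=m.provenance))
        return out
    if spec.mode == "blur":
        for m in members:
            g = np.clip(ndimage.gaussian_filter(m.grid, sigma=3.0 * s), 0.0, 1.0)
            out.append(ProbabilityMap(grid=g, pixel_spacing=m.pixel_spacing, provenance=m.provenance))
        return out
    if spec.mode == "intensity_shift":
        for m in members:
            g = _sigmoid(_logit(m.grid) + 2.0 * s)
            out.append(ProbabilityMap(grid=g, pixel_spacing=m.pixel_spacing, provenance=m.provenance))
        return out
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class PhantomCase:
    """One cohort member: phantom, its reference mask, and simulated members."""

    case_id: str
    hu_image: np.ndarray
    reference: BinaryMask
    members: tuple[ProbabilityMap, ...]
    corrupted: bool


def generate_cohort(
    n_cases: int,
    n_corrupt: int,
    seed: int,
    severity: float = 0.8,
    corruption_mode: str = "streak_artifact",
    sim: EnsembleSimConfig | None = None,
    grid_shape: tuple[int, int] = (256, 256),
) -> list[PhantomCase]:
    """Generate a phantom cohort with a corrupted subset.

    Geometry varies across cases (total muscle area drawn uniformly in
    ±20% of the default), the first ``n_corrupt`` case indices after a
    seeded shuffle receive the corruption. Deterministic in ``seed``.
    """
    if not 0 <= n_corrupt <= n_cases:
        raise ValueError("need 0 <= n_corrupt <= n_cases")
    rng = np.random.default_rng(seed)
    corrupt_ids = set(rng.permutation(n_cases)[:n_corrupt].tolist())
    cases: list[PhantomCase] = []
    # the default 5,800-pixel muscle area is calibrated to the 256×256 body;
    # scale with grid area so components still fit smaller/larger outlines
    area_scale = (grid_shape[0] / 256.0) * (grid_shape[1] / 256.0)
    for i in range(n_cases):
        area = 5800.0 * area_scale * rng.uniform(0.8, 1.2)
        spec = replace(default_spec(seed=int(rng.integers(2**31 - 1)), total_muscle_px=area, grid_shape=grid_shape))
        hu, ref = make_phantom(spec)
        base_cfg = sim or EnsembleSimConfig()
        cfg = replace(base_cfg, seed=int(rng.integers(2**31 - 1)))
        members: Sequence[ProbabilityMap] = simulate_ensemble(ref, cfg)
        is_corrupt = i in corrupt_ids
        if is_corrupt:
            cspec = CorruptionSpec(mode=corruption_mode, severity=severity, seed=int(rng.integers(2**31 - 1)))
            members = corrupt(list(members), cspec)
            hu = corrupt(hu, cspec)
        cases.append(
            PhantomCase(
                case_id=f"phantom-{i:03d}",
                hu_image=hu,
                reference=ref,
                members=tuple(members),
                corrupted=is_corrupt,
            )
        )
    return cases
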