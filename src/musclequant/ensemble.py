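"""Ensemble aggregation of per-member segmentation probability maps.

A segmentation backend (a deep ensemble, stochastic dropout passes, or the
bundled phantom simulator) produces K per-pixel foreground-probability maps
for one axial slice. The consensus segmentation is the pixel-wise mean of the
member maps thresholded at strictly greater than 0.5. The spread across
members is the raw material for every epistemic uncertainty metric in
:mod:`musclequant.uncertainty`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ProbabilityMap",
    "BinaryMask",
    "EnsemblePrediction",
    "aggregate",
    "dropout_aggregate",
    "member_masks",
]

#: Consensus rule: a pixel is muscle iff the mean probability exceeds this,
#: strictly. Probability exactly at the threshold is excluded.
CONSENSUS_THRESHOLD = 0.5


@dataclass(frozen=True)
class BinaryMask:
    """A 2-D segmentation mask with physical pixel spacing.

    ``grid`` holds values in {0, 1} (1 = skeletal muscle);
    ``pixel_spacing`` is (row, col) in millimetres.
    """

    grid: np.ndarray
    pixel_spacing: tuple[float, float]

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise ValueError(f"mask grid must be 2-D, got shape {grid.shape}")
        vals = np.unique(grid)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be exactly 0 or 1")
        if len(self.pixel_spacing) != 2 or min(self.pixel_spacing) <= 0:
            raise ValueError(f"pixel spacing must be two positive values, got {self.pixel_spacing}")
        object.__setattr__(self, "grid", grid.astype(np.uint8))
        object.__setattr__(self, "pixel_spacing", (float(self.pixel_spacing[0]), float(self.pixel_spacing[1])))

    @property
    def pixel_count(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class ProbabilityMap:
    """One model's per-pixel foreground probability on a 2-D grid.

    ``provenance`` identifies the producing member (fold/architecture tag or
    simulator member index); it is carried through to error messages and
    reports but never affects arithmetic.
    """

    grid: np.ndarray
    pixel_spacing: tuple[float, float]
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=np.float64)
        if grid.ndim != 2:
            raise ValueError(f"probability grid must be 2-D, got shape {grid.shape}")
        if grid.min() < 0.0 or grid.max() > 1.0:
            raise ValueError(
                f"probabilities must lie in [0, 1]; member {self.provenance!r} "
                f"has range [{grid.min():.4g}, {grid.max():.4g}]"
            )
        if len(self.pixel_spacing) != 2 or min(self.pixel_spacing) <= 0:
            raise ValueError(f"pixel spacing must be two positive values, got {self.pixel_spacing}")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "pixel_spacing", (float(self.pixel_spacing[0]), float(self.pixel_spacing[1])))

    def threshold(self, cut: float = CONSENSUS_THRESHOLD) -> BinaryMask:
        """Binarize at strict ``p > cut``."""
        return BinaryMask(grid=(self.grid > cut).astype(np.uint8), pixel_spacing=self.pixel_spacing)


@dataclass(frozen=True)
class EnsemblePrediction:
    """K member maps, their pixel-wise mean, and the consensus mask."""

    members: tuple[ProbabilityMap, ...]
    mean_map: ProbabilityMap = field(init=False)
    consensus: BinaryMask = field(init=False)

    def __post_init__(self) -> None:
        members = tuple(self.members)
        if len(members) < 2:
            raise ValueError("an ensemble needs at least 2 members (variance across members is otherwise undefined)")
        _check_common_grid(members)
        stack = np.stack([m.grid for m in members])
        mean_grid = stack.mean(axis=0)
        mean_map = ProbabilityMap(grid=mean_grid, pixel_spacing=members[0].pixel_spacing, provenance="ensemble-mean")
        object.__setattr__(self, "members", members)
        object.__setattr__(self, "mean_map", mean_map)
        object.__setattr__(self, "consensus", mean_map.threshold(CONSENSUS_THRESHOLD))

    @property
    def n_members(self) -> int:
        return len(self.members)

    def member_stack(self) -> np.ndarray:
        """(K, rows, cols) float array of member probabilities."""
        return np.stack([m.grid for m in self.members])


def _check_common_grid(members: Sequence[ProbabilityMap]) -> None:
    ref = members[0]
    for m in members[1:]:
        if m.grid.shape != ref.grid.shape:
            raise ValueError(
                f"member {m.provenance!r} grid shape {m.grid.shape} does not match "
                f"member {ref.provenance!r} shape {ref.grid.shape}"
            )
        if m.pixel_spacing != ref.pixel_spacing:
            raise ValueError(
                f"member {m.provenance!r} spacing {m.pixel_spacing} does not match "
                f"member {ref.provenance!r} spacing {ref.pixel_spacing}"
            )


def aggregate(members: Sequence[ProbabilityMap]) -> EnsemblePrediction:
    """Combine member probability maps into the consensus prediction.

    The mean map is the arithmetic per-pixel mean over members; the consensus
    mask marks pixels whose mean probability is strictly greater than 0.5.
    Raises if fewer than two members are given or if any member's grid shape
    or spacing disagrees (the error names the offending member).
    """
    return EnsemblePrediction(members=tuple(members))


def dropout_aggregate(passes: Sequence[Sequence[ProbabilityMap]]) -> EnsemblePrediction:
    """Two-stage aggregation for stochastic (dropout) inference.

    ``passes`` holds T repeated inference passes, each a list of per-fold
    maps. Per-pass fold means are formed first, then treated as the members
    of the final ensemble. With equal fold counts this equals the grand mean
    of all T×F maps; keeping the two-stage form preserves the per-pass means
    as the members whose spread measures stochastic-inference uncertainty.
    """
    passes = [tuple(p) for p in passes]
    if len(passes) < 2:
        raise ValueError("need at least 2 inference passes")
    fold_count = len(passes[0])
    for i, p in enumerate(passes):
        if len(p) != fold_count:
            raise ValueError(f"ragged passes: pass 0 has {fold_count} folds, pass {i} has {len(p)}")
        if fold_count < 1:
            raise ValueError("each pass needs at least one fold map")
    iteration_means = []
    for t, p in enumerate(passes):
        _check_common_grid(list(p) + list(passes[0]))
        mean_grid = np.stack([m.grid for m in p]).mean(axis=0)
        iteration_means.append(
            ProbabilityMap(grid=mean_grid, pixel_spacing=p[0].pixel_spacing, provenance=f"pass-{t}")
        )
    return EnsemblePrediction(members=tuple(iteration_means))


def member_masks(members: Sequence[ProbabilityMap]) -> list[BinaryMask]:
    """Binarize each member at strict p > 0.5 (mirrors the consensus rule)."""
    if len(members) < 1:
        raise ValueError("need at least one member")
    return [m.threshold(CONSENSUS_THRESHOLD) for m in members]
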