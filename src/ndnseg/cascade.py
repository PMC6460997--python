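"""Coarse-to-fine cascade: three nested binary segmentation stages.

Stage 1 segments the whole tumor (classes {1, 2, 3}), stage 2 the tumor
core ({2, 3}) inside the whole-tumor region, and stage 3 the enhancing
tumor ({3}) inside the core.  At test time each stage's binarized mask
defines a bounding box that, extended by fixed margins of 32 voxels in x
and y and 8 slices in z, becomes the crop fed to the next stage.  During
training the crops derive from ground-truth regions instead.  The three
binary masks are finally fused into a multiclass label map with
later-stage precedence (3 over 2 over 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .preprocess import Patch, sample_patch
from .volio import LabelVolume, MultiModalVolume

logger = logging.getLogger(__name__)

#: test-time ROI extension margins per axis (x, y, z), in voxels
DEFAULT_MARGINS = (32, 32, 8)

#: foreground-probability binarization threshold
DEFAULT_THRESHOLD = 0.5

STAGE_TARGETS: dict[int, frozenset[int]] = {
    1: frozenset({1, 2, 3}),  # whole tumor
    2: frozenset({2, 3}),  # tumor core
    3: frozenset({3}),  # enhancing tumor
}


@dataclass(frozen=True)
class CascadeStage:
    index: int

    def __post_init__(self) -> None:
        if self.index not in STAGE_TARGETS:
            raise ValueError(f"stage index must be 1, 2 or 3, got {self.index}")

    @property
    def targets(self) -> frozenset[int]:
        return STAGE_TARGETS[self.index]


@dataclass(frozen=True)
class ROI:
    """Axis-aligned half-open voxel box inside a volume of ``shape``."""

    box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        for (lo, hi), extent in zip(self.box, self.shape):
            if not 0 <= lo < hi <= extent:
                raise ValueError(f"invalid box {self.box} for shape {self.shape}")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in self.box)

    def crop(self, grid: np.ndarray) -> np.ndarray:
        return grid[self.slices]


def stage_target_mask(labels: LabelVolume, stage: CascadeStage | int) -> np.ndarray:
    """Binary grid: voxel true iff its label belongs to the stage's target set."""
    if isinstance(stage, int):
        stage = CascadeStage(stage)
    return np.isin(labels.labels, list(stage.targets))


def bounding_box(mask: np.ndarray) -> ROI | None:
    """Tight half-open box of the true voxels; ``None`` for an empty mask."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return None
    box = []
    for ax in range(3):
        other = tuple(a for a in range(3) if a != ax)
        nz = np.flatnonzero(mask.any(axis=other))
        box.append((int(nz[0]), int(nz[-1]) + 1))
    return ROI(box=tuple(box), shape=mask.shape)


def extend_roi(
    roi: ROI,
    margins: tuple[int, int, int] = DEFAULT_MARGINS,
    shape: tuple[int, int, int] | None = None,
) -> ROI:
    """Grow the box by a fixed margin per axis, clamped to the volume."""
    shape = roi.shape if shape is None else shape
    box = tuple(
        (max(0, lo - m), min(extent, hi + m))
        for (lo, hi), m, extent in zip(roi.box, margins, shape)
    )
    return ROI(box=box, shape=shape)


def make_stage_training_example(
    volume: MultiModalVolume,
    labels: LabelVolume,
    stage: CascadeStage | int,
    patch_size: tuple[int, int, int],
    rng: np.random.Generator | None = None,
    margins: tuple[int, int, int] = DEFAULT_MARGINS,
    center: str = "tumor",
) -> tuple[Patch, np.ndarray] | None:
    """Ground-truth-cropped training patch and its binary stage target.

    Stage 1 samples from the whole (preprocessed) volume; stages 2 and 3
    first crop the extended ground-truth region of the *previous* stage
    (stage 2 crops to the whole-tumor box, stage 3 to the core box), then
    sample a patch inside the crop.  ``center="tumor"`` centers the patch
    on a uniformly drawn stage-target voxel; ``center="uniform"`` places
    it uniformly inside the crop, which may yield an all-background
    target (the trainer mixes both so the network also sees the empty
    context it will encounter during sliding-window inference).  Returns
    ``None`` with a warning when the stage's parent region is empty
    (e.g. a benign case at stage 3 has no region to refine).
    """
    if isinstance(stage, int):
        stage = CascadeStage(stage)
    if center not in ("tumor", "uniform"):
        raise ValueError(f"unknown patch centering {center!r}")
    rng = np.random.default_rng(rng)

    intens, grid = volume.intensities, labels.labels
    if stage.index > 1:
        parent = CascadeStage(stage.index - 1)
        roi = bounding_box(stage_target_mask(labels, parent))
        if roi is None:
            logger.warning("stage %d: empty parent region, case skipped", stage.index)
            return None
        roi = extend_roi(roi, margins)
        intens = roi.crop(intens)
        grid = roi.crop(grid)

    target_in_crop = np.isin(grid, list(stage.targets))
    if center == "tumor" and not target_in_crop.any():
        logger.warning("stage %d: no target voxels in crop, case skipped", stage.index)
        return None

    # pad to the patch size with the same symmetric rule sample_patch uses
    pad = [(0, 0)] * 3
    for ax in range(3):
        short = patch_size[ax] - grid.shape[ax]
        if short > 0:
            pad[ax] = (short // 2, short - short // 2)
    padded_grid = np.pad(grid, pad)

    if center == "tumor":
        crop_labels = LabelVolume(np.where(target_in_crop, grid, 0))
        patch = sample_patch(
            MultiModalVolume(intens, spacing=volume.spacing, affine=volume.affine),
            crop_labels,
            size=patch_size,
            rng=rng,
        )
        origin = patch.origin
        patch_intens = patch.intensities
    else:
        padded_intens = np.pad(intens, pad + [(0, 0)])
        origin = tuple(
            int(rng.integers(0, padded_grid.shape[ax] - patch_size[ax] + 1))
            for ax in range(3)
        )
        sl = tuple(slice(o, o + s) for o, s in zip(origin, patch_size))
        patch_intens = padded_intens[sl].astype(np.float32)

    sl = tuple(slice(o, o + s) for o, s in zip(origin, patch_size))
    label_patch = padded_grid[sl]
    patch = Patch(patch_intens, label_patch.astype(np.int16), origin)
    target = np.isin(label_patch, list(stage.targets))
    return patch, target


def fuse_stage_masks(m1: np.ndarray, m2: np.ndarray, m3: np.ndarray) -> LabelVolume:
    """Combine the three binary stage masks with later-stage precedence.

    Label 3 where the enhancing mask is set; else 2 where the core mask is
    set; else 1 where the whole-tumor mask is set; else background.
    """
    m1, m2, m3 = (np.asarray(m).astype(bool) for m in (m1, m2, m3))
    if not (m1.shape == m2.shape == m3.shape):
        raise ValueError("stage masks must share shape")
    out = np.zeros(m1.shape, dtype=np.int16)
    out[m1] = 1
    out[m2] = 2
    out[m3] = 3
    return LabelVolume(out)


def run_cascade(
    predictors: Sequence[Callable[[np.ndarray], np.ndarray]],
    volume: MultiModalVolume,
    margins: tuple[int, int, int] = DEFAULT_MARGINS,
    threshold: float = DEFAULT_THRESHOLD,
    roi_log: list | None = None,
) -> tuple[list[np.ndarray], LabelVolume]:
    """Run the three-stage cascade on one (preprocessed) volume.

    Each predictor maps a 4-channel crop ``(x, y, z, 4)`` to a per-voxel
    foreground probability grid of the same spatial shape.  Stage 1 sees
    the full volume; each later stage sees the previous stage's binarized
    mask's bounding box extended by ``margins``.  Masks are re-embedded
    into the full-volume frame before fusion.  An empty stage mask stops
    refinement: remaining stages predict nothing.

    Returns the three full-frame binary masks and the fused label volume.
    ``roi_log`` (if given) collects the per-stage crop boxes.
    """
    if len(predictors) != 3:
        raise ValueError("the cascade needs exactly 3 stage predictors")
    shape = volume.shape
    masks = [np.zeros(shape, dtype=bool) for _ in range(3)]
    roi = ROI(box=tuple((0, s) for s in shape), shape=shape)

    for stage_idx in range(3):
        crop = roi.crop(volume.intensities)
        prob = np.asarray(predictors[stage_idx](crop))
        if prob.shape != crop.shape[:3]:
            raise ValueError(
                f"stage {stage_idx + 1} predictor returned shape {prob.shape}, "
                f"expected {crop.shape[:3]}"
            )
        mask = prob >= threshold
        masks[stage_idx][roi.slices] = mask
        if roi_log is not None:
            roi_log.append({"stage": stage_idx + 1, "box": roi.box})
        if stage_idx == 2:
            break
        next_roi = bounding_box(masks[stage_idx])
        if next_roi is None:
            logger.warning(
                "stage %d produced an empty mask; later stages skipped", stage_idx + 1
            )
            break
        roi = extend_roi(next_roi, margins)

    fused = fuse_stage_masks(*masks)
    return masks, fused
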