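"""Synthetic multimodal tumor phantoms.

Each phantom is a 4-channel volume with nested ellipsoidal tumor
sub-regions inside an elliptical "brain" mask: enhancing tumor innermost
(label 3), a non-enhancing core shell around it (label 2), an edema shell
outermost (label 1), healthy tissue (label 0) inside the mask, and exact
zeros outside it (so border cropping has something to remove).  Each
modality channel is a per-class mean plus Gaussian noise; the four
channels differ only through the class-mean table — enhancing tissue is
bright in the post-contrast T1 channel, edema in the FLAIR channel —
which gives the statistical structure of multimodal MRI without any
attempt at MR-physics realism.  The whole-tumor region of every phantom
is a single connected component by construction.

:func:`inject_artifacts` adds the two defect types the post-processing
stage exists to remove: small disconnected tumor blobs far from the main
component, and a sub-threshold enhancing speck inside the core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volio import (
    MODALITIES,
    CaseRecord,
    LabelVolume,
    MultiModalVolume,
    write_labels,
    write_manifest,
    write_volume,
)

#: per-class modality means, rows = (brain, edema, non-enhancing, enhancing),
#: columns = (t1, t2, t1ce, flair), arbitrary intensity units
DEFAULT_CLASS_MEANS = (
    (1.0, 1.0, 1.0, 1.0),
    (0.8, 1.6, 0.9, 1.8),
    (0.6, 1.3, 0.7, 1.3),
    (0.7, 1.2, 1.9, 1.2),
)


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (64, 64, 32)
    whole_semi_axes: tuple[float, float, float] = (12.0, 12.0, 8.0)
    core_semi_axes: tuple[float, float, float] = (7.0, 7.0, 5.0)
    enhancing_semi_axes: tuple[float, float, float] = (3.0, 3.0, 2.0)
    brain_semi_axes: tuple[float, float, float] = (28.0, 28.0, 14.0)
    class_means: tuple[tuple[float, ...], ...] = DEFAULT_CLASS_MEANS
    noise_std: float = 0.1
    benign: bool = False
    center_jitter: tuple[float, float, float] = (6.0, 6.0, 2.0)
    semi_axis_jitter: float = 0.2  # relative, for dataset generation

    def __post_init__(self) -> None:
        for inner, outer in (
            (self.enhancing_semi_axes, self.core_semi_axes),
            (self.core_semi_axes, self.whole_semi_axes),
        ):
            if any(i > o for i, o in zip(inner, outer)):
                raise ValueError("tumor semi-axes must be nested (enhancing <= core <= whole)")
        if any(a < 1 for a in self.enhancing_semi_axes):
            raise ValueError("semi-axes must be >= 1 voxel")
        if len(self.class_means) != 4 or any(len(row) != 4 for row in self.class_means):
            raise ValueError("class_means must be a 4x4 table")
        if self.noise_std < 0:
            raise ValueError("noise_std must be non-negative")


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    center: tuple[float, float, float],
    semi_axes: tuple[float, float, float],
) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape), indexing="ij")
    d = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return d <= 1.0


def generate_phantom(
    config: PhantomConfig | None = None, rng: np.random.Generator | None = None
) -> tuple[MultiModalVolume, LabelVolume]:
    """One phantom case with a randomized tumor center.

    The tumor ellipsoids must lie entirely inside the brain mask; a
    configuration that places tumor voxels outside it is a hard error.
    """
    config = config or PhantomConfig()
    rng = np.random.default_rng(rng)
    shape = config.shape
    brain_center = tuple((s - 1) / 2.0 for s in shape)
    brain = _ellipsoid_mask(shape, brain_center, config.brain_semi_axes)

    jit = config.center_jitter
    center = tuple(bc + rng.uniform(-j, j) for bc, j in zip(brain_center, jit))
    whole = _ellipsoid_mask(shape, center, config.whole_semi_axes)
    core = _ellipsoid_mask(shape, center, config.core_semi_axes)
    enhancing = _ellipsoid_mask(shape, center, config.enhancing_semi_axes)
    if np.any(whole & ~brain):
        raise ValueError("tumor ellipsoid exceeds the brain mask")

    labels = np.zeros(shape, dtype=np.int16)
    labels[whole] = 1
    labels[core] = 2
    labels[enhancing] = 3
    if config.benign:
        labels[labels == 3] = 2

    means = np.asarray(config.class_means, dtype=np.float64)
    intens = means[labels]  # (X, Y, Z, 4)
    intens = intens + rng.normal(0.0, config.noise_std, size=intens.shape)
    intens[~brain] = 0.0
    return MultiModalVolume(intens.astype(np.float32)), LabelVolume(labels)


def generate_dataset(
    n: int,
    out_dir: Path,
    config: PhantomConfig | None = None,
    rng: np.random.Generator | None = None,
    benign_fraction: float = 0.0,
) -> list[CaseRecord]:
    """Write ``n`` phantoms as NIfTI cases plus a JSON manifest.

    Centers and tumor semi-axes are randomized per case within the
    configured jitter ranges; the first ``round(benign_fraction * n)``
    cases are benign (no enhancing tumor).
    """
    if n < 1:
        raise ValueError("need n >= 1 cases")
    config = config or PhantomConfig()
    rng = np.random.default_rng(rng)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_benign = int(round(benign_fraction * n))

    records = []
    for i in range(n):
        scale = 1.0 + rng.uniform(-config.semi_axis_jitter, config.semi_axis_jitter)
        case_config = PhantomConfig(
            shape=config.shape,
            whole_semi_axes=tuple(a * scale for a in config.whole_semi_axes),
            core_semi_axes=tuple(a * scale for a in config.core_semi_axes),
            enhancing_semi_axes=tuple(max(1.0, a * scale) for a in config.enhancing_semi_axes),
            brain_semi_axes=config.brain_semi_axes,
            class_means=config.class_means,
            noise_std=config.noise_std,
            benign=i < n_benign,
            center_jitter=config.center_jitter,
        )
        volume, labels = generate_phantom(case_config, rng)
        case_id = f"case_{i:03d}"
        case_dir = out_dir / case_id
        case_dir.mkdir(exist_ok=True)
        paths = {m: case_dir / f"{case_id}_{m}.nii.gz" for m in MODALITIES}
        label_path = case_dir / f"{case_id}_labels.nii.gz"
        write_volume(volume, paths)
        write_labels(labels, label_path)
        records.append(CaseRecord(case_id=case_id, modality_paths=paths, label_path=label_path))
    write_manifest(records, out_dir / "manifest.json")
    return records


def inject_artifacts(
    volume: MultiModalVolume,
    labels: LabelVolume,
    k_distractors: int = 3,
    speck_size: int = 3,
    rng: np.random.Generator | None = None,
    distractor_radius: float = 2.0,
    min_gap: int = 3,
) -> tuple[MultiModalVolume, LabelVolume, LabelVolume]:
    """Add removable artifacts to a phantom; returns (volume, labels, truth).

    ``k_distractors`` small edema-labeled blobs are placed inside the brain
    mask at least ``min_gap`` voxels from the main tumor (so they form
    separate connected components), and one ``speck_size``-voxel enhancing
    speck is carved inside the non-enhancing core, disconnected from the
    true enhancing region.  ``truth`` is the pre-injection label grid.
    """
    rng = np.random.default_rng(rng)
    truth = LabelVolume(labels.labels.copy())
    out_labels = labels.labels.copy()
    intens = volume.intensities.copy()
    shape = out_labels.shape
    means = np.asarray(DEFAULT_CLASS_MEANS)

    from scipy import ndimage  # local import keeps module load light

    tumor = out_labels > 0
    brain = np.any(intens != 0, axis=-1)
    # forbidden zone: tumor dilated by the gap plus the blob radius
    grow = int(np.ceil(min_gap + distractor_radius))
    forbidden = ndimage.binary_dilation(tumor, iterations=grow)
    candidates = np.argwhere(brain & ~forbidden)
    if len(candidates) < k_distractors:
        raise ValueError("no room to place disjoint distractor blobs")

    placed = 0
    attempts = 0
    while placed < k_distractors:
        attempts += 1
        if attempts > 100 * max(1, k_distractors):
            raise ValueError("could not place disjoint distractor blobs")
        c = candidates[rng.integers(len(candidates))]
        blob = _ellipsoid_mask(shape, tuple(float(v) for v in c), (distractor_radius,) * 3)
        blob &= brain
        if not blob.any() or np.any(out_labels[blob] > 0):
            continue
        near = ndimage.binary_dilation(
            blob, structure=ndimage.generate_binary_structure(3, 3)
        ) & (out_labels > 0)
        if near.any():
            continue
        out_labels[blob] = 1
        intens[blob] = means[1] + rng.normal(0.0, 0.05, size=(int(blob.sum()), 4))
        placed += 1

    if speck_size > 0:
        # core voxels well away from the true enhancing region
        enh = truth.labels == 3
        if enh.any():
            # full 26-neighborhood dilation: the speck must not be even
            # diagonally adjacent to the true enhancing component
            full = ndimage.generate_binary_structure(3, 3)
            far = ~ndimage.binary_dilation(enh, structure=full, iterations=2)
        else:
            far = np.ones(shape, dtype=bool)
        core_sites = np.argwhere((out_labels == 2) & far)
        if len(core_sites) == 0:
            raise ValueError("no room for an enhancing speck inside the core")
        seed = core_sites[rng.integers(len(core_sites))]
        order = np.argsort(np.abs(core_sites - seed).sum(axis=1))
        chosen = core_sites[order[:speck_size]]
        out_labels[tuple(chosen.T)] = 3
        intens[tuple(chosen.T)] = means[3] + rng.normal(0.0, 0.05, size=(len(chosen), 4))

    return (
        MultiModalVolume(intens, spacing=volume.spacing, affine=volume.affine),
        LabelVolume(out_labels),
        truth,
    )
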