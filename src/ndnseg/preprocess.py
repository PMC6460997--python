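"""Intensity normalization, border removal, slab selection, patch sampling.

Each modality is z-scored per patient over the whole volume (population
standard deviation; constant channels map to zeros).  Uninformative black
borders are cropped along x and y only, and the central 70% of z-slices is
kept, mirroring the acquisition geometry where the head and tail of the
stack carry no anatomy.  Training patches of a fixed size (default
96x96x48) are sampled centered on tumor voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volio import LabelVolume, MultiModalVolume

DEFAULT_PATCH_SIZE = (96, 96, 48)
DEFAULT_SLAB_FRACTION = 0.7


@dataclass
class CropReport:
    """Half-open kept box per axis and the original shape."""

    box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    original_shape: tuple[int, int, int]


@dataclass
class Patch:
    """Fixed-size 4-channel intensity grid with matching labels.

    ``origin`` is the (x, y, z) offset of the patch into the (possibly
    zero-padded) source volume.
    """

    intensities: np.ndarray  # (px, py, pz, 4)
    labels: np.ndarray  # (px, py, pz)
    origin: tuple[int, int, int]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[:3]


def zscore_normalize(volume: MultiModalVolume) -> MultiModalVolume:
    """Per-channel z-score: subtract the mean, divide by the population
    standard deviation.  Channels with zero variance map to all-zeros."""
    x = volume.intensities
    if not np.all(np.isfinite(x)):
        raise ValueError("cannot normalize non-finite intensities")
    mean = x.mean(axis=(0, 1, 2), keepdims=True)
    std = x.std(axis=(0, 1, 2), keepdims=True)  # population (divide-by-n)
    out = np.where(std > 0, (x - mean) / np.where(std > 0, std, 1.0), 0.0)
    return MultiModalVolume(out.astype(np.float32), spacing=volume.spacing, affine=volume.affine)


def crop_black_borders(
    volume: MultiModalVolume, labels: LabelVolume | None = None
) -> tuple[MultiModalVolume, LabelVolume | None, CropReport]:
    """Crop x/y to the tight bounding box of voxels nonzero in any channel.

    The z-axis is left untouched (slab selection handles it separately);
    labels are cropped with the identical box.
    """
    any_signal = np.any(volume.intensities != 0, axis=-1)  # (X, Y, Z)
    if not any_signal.any():
        raise ValueError("volume is entirely zero; nothing to keep")
    xs = np.flatnonzero(any_signal.any(axis=(1, 2)))
    ys = np.flatnonzero(any_signal.any(axis=(0, 2)))
    x_lo, x_hi = int(xs[0]), int(xs[-1]) + 1
    y_lo, y_hi = int(ys[0]), int(ys[-1]) + 1
    z_lo, z_hi = 0, volume.shape[2]
    report = CropReport(
        box=((x_lo, x_hi), (y_lo, y_hi), (z_lo, z_hi)),
        original_shape=volume.shape,
    )
    cropped = MultiModalVolume(
        volume.intensities[x_lo:x_hi, y_lo:y_hi],
        spacing=volume.spacing,
        affine=volume.affine,
    )
    cropped_labels = None
    if labels is not None:
        cropped_labels = LabelVolume(labels.labels[x_lo:x_hi, y_lo:y_hi])
    return cropped, cropped_labels, report


def select_middle_slab(
    volume: MultiModalVolume,
    labels: LabelVolume | None = None,
    fraction: float = DEFAULT_SLAB_FRACTION,
) -> tuple[MultiModalVolume, LabelVolume | None, tuple[int, int]]:
    """Keep ``k = round(fraction * Z)`` consecutive central z-slices.

    When two centerings exist the lower start index is used.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    z = volume.shape[2]
    k = int(round(fraction * z))
    if k < 1:
        raise ValueError(f"slab of {k} slices from Z={z}, fraction={fraction}")
    start = (z - k) // 2
    stop = start + k
    slab = MultiModalVolume(
        volume.intensities[:, :, start:stop], spacing=volume.spacing, affine=volume.affine
    )
    slab_labels = None
    if labels is not None:
        slab_labels = LabelVolume(labels.labels[:, :, start:stop])
    return slab, slab_labels, (start, stop)


def sample_patch(
    volume: MultiModalVolume,
    labels: LabelVolume,
    size: tuple[int, int, int] = DEFAULT_PATCH_SIZE,
    rng: np.random.Generator | None = None,
) -> Patch:
    """Sample a tumor-centered fixed-size patch.

    The center is drawn uniformly from tumor voxels (label > 0), then the
    patch box is clamped to lie within bounds.  Axes smaller than the patch
    are zero-padded symmetrically first, so the output always has exactly
    ``size`` voxels per axis.
    """
    rng = np.random.default_rng(rng)
    intens, grid = volume.intensities, labels.labels
    if intens.shape[:3] != grid.shape:
        raise ValueError("volume and labels shapes differ")

    # pad any axis smaller than the patch
    pad = [(0, 0)] * 3
    for ax in range(3):
        short = size[ax] - grid.shape[ax]
        if short > 0:
            pad[ax] = (short // 2, short - short // 2)
    if any(p != (0, 0) for p in pad):
        intens = np.pad(intens, pad + [(0, 0)])
        grid = np.pad(grid, pad)

    tumor = np.argwhere(grid > 0)
    if len(tumor) == 0:
        raise ValueError("no tumor voxels to center a patch on")
    center = tumor[rng.integers(len(tumor))]

    origin = []
    for ax in range(3):
        lo = int(center[ax]) - size[ax] // 2
        lo = max(0, min(lo, grid.shape[ax] - size[ax]))
        origin.append(lo)
    sl = tuple(slice(o, o + s) for o, s in zip(origin, size))
    return Patch(
        intensities=intens[sl].astype(np.float32),
        labels=grid[sl].astype(np.int16),
        origin=tuple(origin),
    )
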