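"""Seeded, label-consistent data augmentation for training patches.

Four operations in a fixed order — axis flips, in-plane rotation, gamma
correction, elastic distortion — each applied identically to intensities
and labels where geometry is involved.  Intensities are interpolated
linearly, labels nearest-neighbor, so the label alphabet never grows.
Everything is driven by an explicit ``numpy`` generator: the same seed
reproduces the same augmented patch bit-for-bit.

Rotation is restricted to the axial (x-y) plane: clinical tumor volumes
have a much shorter z-extent than in-plane extent, and through-plane
rotation of such anisotropic stacks destroys anatomy.  Gamma correction is
applied in min-max-normalized space because inputs are z-scored and may be
negative.  Elastic-distortion magnitudes are package defaults, not
literature values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .preprocess import Patch


@dataclass
class AugmentConfig:
    flip_prob: tuple[float, float, float] = (0.5, 0.5, 0.5)
    rotation_range: tuple[float, float] = (-15.0, 15.0)  # degrees, axial plane
    gamma_range: tuple[float, float] = (0.4, 1.6)
    elastic_alpha: float = 10.0  # displacement magnitude, voxels
    elastic_sigma: float = 4.0  # Gaussian smoothing of the field, voxels
    enable_flip: bool = True
    enable_rotate: bool = True
    enable_gamma: bool = True
    enable_elastic: bool = True

    def __post_init__(self) -> None:
        if not all(0 <= p <= 1 for p in self.flip_prob):
            raise ValueError("flip probabilities must lie in [0, 1]")
        if self.rotation_range[0] > self.rotation_range[1]:
            raise ValueError("empty rotation range")
        if self.gamma_range[0] > self.gamma_range[1] or self.gamma_range[0] <= 0:
            raise ValueError("gamma range must be positive and non-empty")
        if self.elastic_alpha < 0 or self.elastic_sigma < 0:
            raise ValueError("elastic alpha/sigma must be non-negative")
        if self.elastic_alpha > 0 and self.elastic_sigma == 0:
            raise ValueError("elastic distortion needs sigma > 0")


def random_flip(patch: Patch, config: AugmentConfig, rng: np.random.Generator) -> Patch:
    """Independently reverse each spatial axis with the configured probability."""
    draws = rng.random(3)
    intens, labels = patch.intensities, patch.labels
    for ax in range(3):
        if draws[ax] < config.flip_prob[ax]:
            intens = np.flip(intens, axis=ax)
            labels = np.flip(labels, axis=ax)
    return Patch(np.ascontiguousarray(intens), np.ascontiguousarray(labels), patch.origin)


def random_rotate(patch: Patch, config: AugmentConfig, rng: np.random.Generator) -> Patch:
    """Rotate about the z-axis by an angle drawn uniformly from the range."""
    lo, hi = config.rotation_range
    angle = float(rng.uniform(lo, hi))
    if angle == 0.0:
        return patch
    intens = ndimage.rotate(
        patch.intensities, angle, axes=(0, 1), reshape=False, order=1, mode="constant", cval=0.0
    )
    labels = ndimage.rotate(
        patch.labels, angle, axes=(0, 1), reshape=False, order=0, mode="constant", cval=0
    )
    return Patch(intens.astype(np.float32), labels.astype(np.int16), patch.origin)


def random_gamma(patch: Patch, config: AugmentConfig, rng: np.random.Generator) -> Patch:
    """Per-channel gamma correction in min-max space.

    Each channel is rescaled to [0, 1], raised to a random power gamma, and
    rescaled back to its original min/max, so channel extrema are preserved.
    Constant channels are left unchanged.  Labels untouched.
    """
    gamma = float(rng.uniform(*config.gamma_range))
    intens = patch.intensities.copy()
    for c in range(intens.shape[-1]):
        ch = intens[..., c]
        lo, hi = float(ch.min()), float(ch.max())
        if hi <= lo:
            continue
        unit = (ch - lo) / (hi - lo)
        intens[..., c] = unit**gamma * (hi - lo) + lo
    return Patch(intens, patch.labels, patch.origin)


def _displacement_field(
    shape: tuple[int, int, int], alpha: float, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian-smoothed iid noise scaled by alpha, one field per axis."""
    field = np.empty((3,) + shape, dtype=np.float64)
    for ax in range(3):
        noise = rng.uniform(-1, 1, size=shape)
        field[ax] = ndimage.gaussian_filter(noise, sigma) * alpha
    return field


def elastic_distort(patch: Patch, config: AugmentConfig, rng: np.random.Generator) -> Patch:
    """Warp with a dense random displacement field.

    The field is iid uniform noise smoothed by a Gaussian of width ``sigma``
    then scaled by ``alpha``; its magnitude is therefore bounded by
    ``alpha * max|smoothed noise|``.
    """
    if config.elastic_alpha == 0:
        return patch
    shape = patch.shape
    field = _displacement_field(shape, config.elastic_alpha, config.elastic_sigma, rng)
    coords = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape), indexing="ij")
    warped = [coords[ax] + field[ax] for ax in range(3)]

    intens = np.empty_like(patch.intensities)
    for c in range(patch.intensities.shape[-1]):
        intens[..., c] = ndimage.map_coordinates(
            patch.intensities[..., c], warped, order=1, mode="constant", cval=0.0
        )
    labels = ndimage.map_coordinates(
        patch.labels, warped, order=0, mode="constant", cval=0
    ).astype(np.int16)
    return Patch(intens, labels, patch.origin)


def augment_pipeline(patch: Patch, config: AugmentConfig, rng: np.random.Generator) -> Patch:
    """flip -> rotate -> gamma -> elastic, honoring the enable flags."""
    if config.enable_flip:
        patch = random_flip(patch, config, rng)
    if config.enable_rotate:
        patch = random_rotate(patch, config, rng)
    if config.enable_gamma:
        patch = random_gamma(patch, config, rng)
    if config.enable_elastic:
        patch = elastic_distort(patch, config, rng)
    return patch
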