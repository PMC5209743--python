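"""Single-nucleus image preparation.

Turns multi-plane two-channel fluorescence stacks into projected,
background-subtracted, segmented and gray-level-quantized single-nucleus
images — the inputs of the texture engine.  All operations are
deterministic; coordinates are (row, col), 0-based, origin top-left.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import disk, opening

from .errors import (
    BadKernelError,
    BadRadiusError,
    EmptyStackError,
    NoObjectError,
    ShapeMismatchError,
)

#: Default physical pixel size: a 23.25 x 23.25 um field at 1024 x 1024 px.
DEFAULT_PIXEL_SIZE_UM = 23.25 / 1024

#: Sentinel gray level for out-of-mask pixels of a quantized image.
QUANT_SENTINEL = -1


class Channel(enum.Enum):
    """Fluorescence channel identity of an image."""

    GREEN_K4 = "green_K4"      # H3K4me3, activating mark
    RED_K27 = "red_K27"        # H3K27me3, repressive mark
    COMPOSITE = "composite"


@dataclass(frozen=True)
class ImageStack:
    """A 3-D (z, row, col) fluorescence z-stack of one channel."""

    planes: np.ndarray
    channel: Channel = Channel.COMPOSITE
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_step_um: float | None = None

    def __post_init__(self):
        planes = np.asarray(self.planes, dtype=float)
        if planes.ndim != 3 or planes.shape[0] < 1:
            raise EmptyStackError("stack must be a non-empty (z, row, col) array")
        if not np.all(np.isfinite(planes)) or np.any(planes < 0):
            raise ValueError("stack intensities must be finite and non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "planes", planes)

    @property
    def n_planes(self) -> int:
        return self.planes.shape[0]


@dataclass(frozen=True)
class NucleusImage:
    """A projected 2-D image with a boolean nucleus mask and pixel metadata."""

    pixels: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    channel: Channel = Channel.COMPOSITE

    def __post_init__(self):
        pixels = np.asarray(self.pixels, dtype=float)
        if pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")
        if not np.all(np.isfinite(pixels)):
            raise ValueError("pixels must be finite")
        mask = self.mask
        if mask is None:
            mask = np.ones(pixels.shape, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != pixels.shape:
            raise ShapeMismatchError("mask shape must match pixels")
        object.__setattr__(self, "pixels", pixels)
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def masked_values(self) -> np.ndarray:
        return self.pixels[self.mask]


@dataclass(frozen=True)
class QuantizedImage:
    """Gray-level quantized image; out-of-mask pixels carry a sentinel."""

    levels: np.ndarray
    n_levels: int
    mask: np.ndarray

    def __post_init__(self):
        levels = np.asarray(self.levels)
        mask = np.asarray(self.mask, dtype=bool)
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        inmask = levels[mask]
        if inmask.size and (inmask.min() < 0 or inmask.max() >= self.n_levels):
            raise ValueError("in-mask levels must lie in [0, n_levels)")
        object.__setattr__(self, "levels", levels.astype(np.int64))
        object.__setattr__(self, "mask", mask)


def average_project(stack: ImageStack) -> NucleusImage:
    """Arithmetic-mean projection of a z-stack along z.

    The resulting mask is all-true; segmentation comes later.
    """
    pixels = stack.planes.mean(axis=0)
    return NucleusImage(
        pixels=pixels,
        mask=np.ones(pixels.shape, dtype=bool),
        pixel_size_um=stack.pixel_size_um,
        channel=stack.channel,
    )


def subtract_background(img: NucleusImage, radius: int = 50) -> NucleusImage:
    """Rolling-ball-style background removal by grayscale morphological opening.

    The opening with a disk of ``radius`` estimates the smooth background;
    subtracting it leaves compact bright structure.  Output is clipped at 0.
    """
    if radius < 1:
        raise BadRadiusError("radius must be >= 1")
    if 2 * radius + 1 > min(img.shape):
        raise BadRadiusError(
            f"radius {radius} exceeds image extent {img.shape}"
        )
    background = opening(img.pixels, disk(radius))
    cleaned = np.clip(img.pixels - background, 0.0, None)
    return replace(img, pixels=cleaned)


def segment_nucleus(
    img: NucleusImage,
    min_area_px: int = 100,
    sigma: float = 2.0,
) -> NucleusImage:
    """Isolate the nucleus: Gaussian smooth, Otsu threshold, fill holes,
    keep the largest connected component.

    Raises ``NO_OBJECT`` when no component of at least ``min_area_px``
    survives thresholding (e.g. a zero-contrast image).
    """
    pixels = img.pixels
    if pixels.max() <= pixels.min():
        raise NoObjectError("image has no dynamic range")
    smoothed = gaussian(pixels, sigma=sigma, preserve_range=True)
    thr = threshold_otsu(smoothed)
    binary = smoothed > thr
    if not binary.any():
        raise NoObjectError("nothing above threshold")
    binary = ndimage.binary_fill_holes(binary)
    labels, n = ndimage.label(binary)
    if n == 0:
        raise NoObjectError("no connected component")
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(areas)) + 1
    if areas[best - 1] < min_area_px:
        raise NoObjectError(
            f"largest component ({int(areas[best - 1])} px) below min_area_px={min_area_px}"
        )
    return replace(img, mask=labels == best)


def compose_channels(
    green: NucleusImage,
    red: NucleusImage,
    w_green: float = 0.5,
    w_red: float = 0.5,
) -> NucleusImage:
    """Weighted overlay of the two channels on their shared mask.

    Each channel is min-max normalized to [0, 1] over the shared mask first,
    so the overlay reflects texture, not absolute brightness imbalance.
    """
    if green.shape != red.shape:
        raise ShapeMismatchError(f"{green.shape} vs {red.shape}")
    if w_green < 0 or w_red < 0 or w_green + w_red <= 0:
        raise ValueError("weights must be >= 0 and sum positive")
    mask = green.mask & red.mask

    def _norm(pix: np.ndarray) -> np.ndarray:
        vals = pix[mask]
        lo, hi = vals.min(), vals.max()
        if hi > lo:
            return (pix - lo) / (hi - lo)
        return np.zeros_like(pix)

    combined = w_green * _norm(green.pixels) + w_red * _norm(red.pixels)
    return NucleusImage(
        pixels=combined,
        mask=mask,
        pixel_size_um=green.pixel_size_um,
        channel=Channel.COMPOSITE,
    )


def quantize(img: NucleusImage, n_levels: int = 16) -> QuantizedImage:
    """Min-max quantize in-mask intensities to ``n_levels`` gray levels.

    level = min(Ng-1, floor((v - vmin) / (vmax - vmin) * Ng)); a zero-range
    image maps to level 0 everywhere.  The rule is invariant to any strictly
    increasing affine transform of the intensities.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if not img.mask.any():
        raise ValueError("mask is empty")
    vals = img.masked_values()
    vmin, vmax = vals.min(), vals.max()
    levels = np.full(img.shape, QUANT_SENTINEL, dtype=np.int64)
    if vmax > vmin:
        scaled = (img.pixels - vmin) / (vmax - vmin) * n_levels
        lv = np.minimum(np.floor(scaled), n_levels - 1).astype(np.int64)
        levels[img.mask] = lv[img.mask]
    else:
        levels[img.mask] = 0
    return QuantizedImage(levels=levels, n_levels=n_levels, mask=img.mask.copy())


def median_degrade(img: NucleusImage, kernel: int) -> NucleusImage:
    """Median-filter the image to emulate a coarser optical resolution.

    ``kernel`` is the odd side of the square neighborhood; 1 is the identity.
    Edges are replicated ("nearest" mode).
    """
    if kernel < 1 or kernel % 2 == 0:
        raise BadKernelError("kernel must be odd and >= 1")
    if kernel == 1:
        return img
    filtered = ndimage.median_filter(img.pixels, size=kernel, mode="nearest")
    return replace(img, pixels=filtered)
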