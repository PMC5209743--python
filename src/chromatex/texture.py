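"""Grey-level co-occurrence matrices and the 104-value texture descriptor.

The descriptor of a nucleus is built in three stages:

1. a symmetric four-direction GLCM is accumulated in a sliding window
   around every in-mask pixel, at pair distances of 1 and 2 px;
2. the 13 Haralick statistics of each window's GLCM give 13 feature
   maps per distance;
3. mean, standard deviation, skewness and kurtosis of each map over its
   valid pixels give 13 x 4 x 2 = 104 scalars per nucleus.

Entropies are in bits.  The canonical descriptor order is feature-major
(Haralick 1973 order), then statistic (mean, std, skew, kurt), then
distance (1, 2); names follow ``{feature}_{stat}_d{distance}``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .errors import EmptySampleError, NoPairsError, NoValidWindowsError
from .image import NucleusImage, QuantizedImage, quantize

FEATURE_NAMES: tuple[str, ...] = (
    "energy",
    "contrast",
    "correlation",
    "variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "info_correlation_1",
    "info_correlation_2",
)

STAT_NAMES: tuple[str, ...] = ("mean", "std", "skew", "kurt")

DISTANCES: tuple[int, ...] = (1, 2)

#: The four standard direction offsets (drow, dcol) at unit distance.
STANDARD_DIRECTIONS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))


class FeatureSet13(NamedTuple):
    """The 13 Haralick texture statistics of one GLCM."""

    energy: float
    contrast: float
    correlation: float
    variance: float
    inverse_difference_moment: float
    sum_average: float
    sum_variance: float
    sum_entropy: float
    entropy: float
    difference_variance: float
    difference_entropy: float
    info_correlation_1: float
    info_correlation_2: float


@dataclass(frozen=True)
class GLCM:
    """A normalized grey-level co-occurrence matrix."""

    p: np.ndarray
    n_levels: int
    distance: int
    directions: tuple[tuple[int, int], ...]
    symmetric: bool
    total_pairs: int

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if np.any(p < 0):
            raise ValueError("GLCM probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("GLCM must be normalized to sum 1")
        if self.symmetric and not np.allclose(p, p.T, atol=1e-12):
            raise ValueError("symmetric GLCM must equal its transpose")
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class FeatureMaps:
    """13 named per-pixel feature maps plus their shared validity mask."""

    maps: np.ndarray          # (13, rows, cols), NaN outside `valid`
    valid: np.ndarray         # boolean, subset of the nucleus mask
    distance: int
    window: int

    def __getitem__(self, feature: str) -> np.ndarray:
        return self.maps[FEATURE_NAMES.index(feature)]


def descriptor_names() -> list[str]:
    """The canonical ordered names of the 104 descriptors."""
    return [
        f"{feat}_{stat}_d{d}"
        for feat in FEATURE_NAMES
        for stat in STAT_NAMES
        for d in DISTANCES
    ]


@dataclass(frozen=True)
class TextureConfig:
    """Parameters of descriptor extraction.

    n_levels: grey levels Ng of the quantized alphabet (windowed default 16).
    window: odd side of the sliding window, in px.
    distances: GLCM pair distances, in px.
    min_pairs: minimum in-mask pairs for a window to be valid.
    mode: "windowed" (moments over per-pixel feature maps, default) or
        "directional" (moments over the four whole-image per-direction
        feature values; provided for comparison, not the default).
    """

    n_levels: int = 16
    window: int = 9
    distances: tuple[int, ...] = DISTANCES
    min_pairs: int = 8
    mode: str = "windowed"

    def __post_init__(self):
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be odd and >= 3")
        if self.mode not in ("windowed", "directional"):
            raise ValueError("mode must be 'windowed' or 'directional'")


def compute_glcm(
    qimg: QuantizedImage,
    distance: int = 1,
    directions: Sequence[tuple[int, int]] | None = None,
    symmetric: bool = True,
) -> GLCM:
    """Accumulate a GLCM over all in-mask pixel pairs of a quantized image.

    Both ends of a pair must be in-mask.  Offsets default to the four
    standard directions scaled by ``distance``.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if directions is None:
        offs = [(dr * distance, dc * distance) for dr, dc in STANDARD_DIRECTIONS]
    else:
        offs = [tuple(o) for o in directions]
    offsets = np.asarray(offs, dtype=np.int64).reshape(-1, 2)
    counts = np.zeros((qimg.n_levels, qimg.n_levels))
    # sentinel-coded out-of-mask levels are masked out, but clip defensively
    levels = np.clip(qimg.levels, 0, qimg.n_levels - 1)
    n_pairs = _kernels.accumulate_glcm(
        levels, qimg.mask, offsets, symmetric, counts
    )
    if n_pairs == 0:
        raise NoPairsError("no valid in-mask pixel pairs at this offset")
    p = counts / counts.sum()
    return GLCM(
        p=p,
        n_levels=qimg.n_levels,
        distance=distance,
        directions=tuple(offs),
        symmetric=symmetric,
        total_pairs=n_pairs,
    )


def haralick13(glcm: GLCM) -> FeatureSet13:
    """Evaluate the 13 Haralick statistics of a normalized GLCM."""
    out = np.empty(_kernels.N_FEATURES)
    _kernels.haralick_features(np.ascontiguousarray(glcm.p, dtype=float), out)
    return FeatureSet13(*out)


def texture_maps(
    qimg: QuantizedImage,
    window: int = 9,
    distance: int = 1,
    min_pairs: int = 8,
) -> FeatureMaps:
    """Sliding-window Haralick feature maps over the nucleus mask.

    Each in-mask pixel gets a symmetric four-direction GLCM from its
    window x window neighborhood (in-mask pairs only); windows with fewer
    than ``min_pairs`` pairs are dropped from the validity mask.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    levels = np.clip(qimg.levels, 0, qimg.n_levels - 1)
    maps, valid = _kernels.texture_map_kernel(
        np.ascontiguousarray(levels),
        np.ascontiguousarray(qimg.mask),
        qimg.n_levels,
        window,
        distance,
        min_pairs,
    )
    if not valid.any():
        raise NoValidWindowsError("no window holds enough in-mask pairs")
    return FeatureMaps(maps=maps, valid=valid, distance=distance, window=window)


def moment_stats(values) -> tuple[float, float, float, float]:
    """(mean, sample std, skewness, excess kurtosis) of a sample.

    Skewness is the biased moment coefficient m3/m2^1.5 and kurtosis the
    biased excess m4/m2^2 - 3; a zero-variance sample returns 0 for both
    by convention (and sample std 0 for a single value).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise EmptySampleError("need at least one value")
    mean = float(v.mean())
    d = v - mean
    m2 = float(np.mean(d**2))
    if v.size > 1:
        std = float(v.std(ddof=1))
    else:
        std = 0.0
    if m2 <= 0.0:
        return mean, std, 0.0, 0.0
    m3 = float(np.mean(d**3))
    m4 = float(np.mean(d**4))
    return mean, std, m3 / m2**1.5, m4 / m2**2 - 3.0


def _directional_features(
    qimg: QuantizedImage, distance: int
) -> dict[str, np.ndarray]:
    """Whole-image per-direction features: 4 values per feature."""
    per_feature: dict[str, list[float]] = {f: [] for f in FEATURE_NAMES}
    for dr, dc in STANDARD_DIRECTIONS:
        glcm = compute_glcm(
            qimg, distance=distance, directions=[(dr * distance, dc * distance)]
        )
        feats = haralick13(glcm)
        for name, value in zip(FEATURE_NAMES, feats):
            per_feature[name].append(value)
    return {k: np.asarray(v) for k, v in per_feature.items()}


def descriptor_vector(
    img: NucleusImage, cfg: TextureConfig | None = None
) -> pd.Series:
    """The 104-value texture descriptor of one segmented nucleus.

    Quantizes the in-mask intensities, builds the 13 feature maps at each
    distance, and summarizes each map with the four moments.  Returns an
    ordered, named pandas Series of exactly 104 finite values.
    """
    cfg = cfg or TextureConfig()
    qimg = quantize(img, cfg.n_levels)
    values: dict[str, float] = {}
    for d in cfg.distances:
        if cfg.mode == "windowed":
            fmaps = texture_maps(
                qimg, window=cfg.window, distance=d, min_pairs=cfg.min_pairs
            )
            for fi, feat in enumerate(FEATURE_NAMES):
                stats = moment_stats(fmaps.maps[fi][fmaps.valid])
                for stat_name, value in zip(STAT_NAMES, stats):
                    values[f"{feat}_{stat_name}_d{d}"] = value
        else:
            per_feature = _directional_features(qimg, d)
            for feat in FEATURE_NAMES:
                stats = moment_stats(per_feature[feat])
                for stat_name, value in zip(STAT_NAMES, stats):
                    values[f"{feat}_{stat_name}_d{d}"] = value
    names = [
        f"{feat}_{stat}_d{d}"
        for feat in FEATURE_NAMES
        for stat in STAT_NAMES
        for d in cfg.distances
    ]
    ordered = pd.Series([values[n] for n in names], index=names, dtype=float)
    if not np.all(np.isfinite(ordered.to_numpy())):
        raise ValueError("descriptor vector contains non-finite values")
    return ordered
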