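"""End-to-end orchestration: images in, descriptors and parsed phenotypes out.

These are the functions the CLI, the examples and the acceptance script
drive; each is a thin composition of the image, texture and analytics
modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analytics import (
    DescriptorDataset,
    Embedding,
    evaluate_classifier,
    fit_pca3,
    kmeans_centroids,
    phenotype_parsing_index,
    train_classifier,
)
from .errors import MissingCalibrationError
from .image import (
    ImageStack,
    NucleusImage,
    average_project,
    compose_channels,
    median_degrade,
    segment_nucleus,
    subtract_background,
)
from .texture import TextureConfig, descriptor_vector

log = logging.getLogger("chromatex")


@dataclass(frozen=True)
class PreprocessConfig:
    """Projection/cleanup/segmentation parameters."""

    background_radius: int = 50          # at 1024x1024; scaled to image size
    segment_sigma: float = 2.0
    min_area_px: int = 100
    w_green: float = 0.5
    w_red: float = 0.5
    median_kernel: int = 1               # 1 = no resolution degradation

    def scaled_radius(self, shape: tuple[int, int]) -> int:
        return max(1, round(self.background_radius * min(shape) / 1024))


def prepare_nucleus(
    green: ImageStack,
    red: ImageStack,
    pre: PreprocessConfig | None = None,
    mask: np.ndarray | None = None,
) -> NucleusImage:
    """Project, clean, segment and overlay a two-channel stack.

    With a precomputed ``mask`` the segmentation step is skipped.  The
    composite is segmented on the summed channels, then both channels are
    min-max normalized over the mask and averaged with the configured
    weights.
    """
    pre = pre or PreprocessConfig()
    g = average_project(green)
    r = average_project(red)
    radius = pre.scaled_radius(g.shape)
    g = subtract_background(g, radius)
    r = subtract_background(r, radius)
    if pre.median_kernel > 1:
        g = median_degrade(g, pre.median_kernel)
        r = median_degrade(r, pre.median_kernel)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
    else:
        total = NucleusImage(g.pixels + r.pixels, pixel_size_um=g.pixel_size_um)
        mask = segment_nucleus(
            total, min_area_px=pre.min_area_px, sigma=pre.segment_sigma
        ).mask
    g = NucleusImage(g.pixels, mask, g.pixel_size_um, g.channel)
    r = NucleusImage(r.pixels, mask, r.pixel_size_um, r.channel)
    return compose_channels(g, r, pre.w_green, pre.w_red)


def cohort_descriptors(
    cohort,
    texture_cfg: TextureConfig | None = None,
    pre: PreprocessConfig | None = None,
    use_truth_masks: bool = True,
) -> DescriptorDataset:
    """Extract the 104-descriptor vector for every phantom of a cohort."""
    texture_cfg = texture_cfg or TextureConfig()
    rows, labels = [], []
    for member in cohort.members:
        green, red = member.phantom.stacks()
        truth = member.phantom.mask if use_truth_masks else None
        nucleus = prepare_nucleus(green, red, pre, mask=truth)
        rows.append(descriptor_vector(nucleus, texture_cfg))
        labels.append(member.label)
    return DescriptorDataset.from_rows(rows, labels)


@dataclass
class ParseReport:
    """Calibrated parsing of a descriptor dataset.

    centroids: per-condition k-means (k=1) centroid in PC score space;
    ppi: phenotype parsing index per condition on the calibration axis.
    """

    embedding: Embedding
    classifier: object
    centroids: pd.DataFrame               # index=condition, cols PC1..PC3
    ppi: pd.Series
    evaluation: object | None = None


def parse_phenotypes(
    data: DescriptorDataset,
    open_condition: str,
    closed_condition: str,
    seed: int = 0,
    evaluate: bool = True,
) -> ParseReport:
    """Calibrate PCA+SVM on two reference cohorts and parse all conditions.

    The open/closed calibration conditions play the roles of the
    strongest KMT-inhibitor cohorts; every condition's k-means centroid is
    then placed on the closed-to-open axis as a phenotype parsing index,
    so PPI(open) = +1 and PPI(closed) = -1 by construction.
    """
    conditions = list(dict.fromkeys(data.condition))
    for cond in (open_condition, closed_condition):
        if cond not in conditions:
            raise MissingCalibrationError(f"condition {cond!r} not in dataset")
    embedding = fit_pca3(data)
    open_set = data.subset(open_condition)
    closed_set = data.subset(closed_condition)
    classifier = train_classifier(open_set, closed_set, embedding, seed=seed)
    centroid_rows = {}
    for cond in conditions:
        scores = embedding.transform(data.subset(cond).features)
        centroid_rows[cond] = kmeans_centroids(scores, k=1, seed=seed).centroids[0]
    centroids = pd.DataFrame(
        centroid_rows, index=["PC1", "PC2", "PC3"]
    ).T.loc[conditions]
    open_ref = centroids.loc[open_condition].to_numpy()
    closed_ref = centroids.loc[closed_condition].to_numpy()
    ppi = pd.Series(
        {
            cond: phenotype_parsing_index(
                centroids.loc[cond].to_numpy(), open_ref, closed_ref
            )
            for cond in conditions
        },
        name="ppi",
    ).loc[conditions]
    evaluation = None
    min_count = int(data.condition.value_counts().min())
    if evaluate and len(conditions) >= 2 and min_count >= 4:
        evaluation = evaluate_classifier(data, seed=seed)
    return ParseReport(
        embedding=embedding,
        classifier=classifier,
        centroids=centroids,
        ppi=ppi,
        evaluation=evaluation,
    )
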