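"""Whole-organism segmentation from the transmitted-light channel.

A single *Daphnia magna* sits in each imaged well on a brighter, roughly
uniform background.  The mask is built from the brightness difference
between each pixel and the well background: the transmitted-light image is
Gaussian-smoothed, the background level is estimated as the median of a
border band (the organism never touches the image edge at the 4x field of
view), and pixels whose deviation from background exceeds an Otsu-derived
threshold are classified as organism.  Morphological closing, hole filling
and a minimum-area filter remove camera noise and small extra-organismal
dye aggregates.

The segment count is reported BEFORE any largest-component selection: a
count other than 1 marks the z-level as incorrect, it is never repaired.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

__all__ = ["SegmentationParams", "OrganismMask", "segment_organism",
           "z_level_correct"]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the brightness-difference mask.

    ``min_contrast_snr`` guards against labelling pure noise: the Otsu
    threshold on the |TL - background| image must exceed this multiple of
    the robust noise scale measured in the border band, otherwise the well
    is declared empty.
    """

    smoothing_sigma_px: float = 2.0
    min_object_area_px: int = 500
    closing_radius_px: int = 2
    fill_holes: bool = True
    polarity: Literal["auto", "dark_object", "bright_object"] = "auto"
    border_band_px: int = 8
    min_contrast_snr: float = 4.0

    def __post_init__(self):
        if self.smoothing_sigma_px < 0 or self.closing_radius_px < 0:
            raise ValueError("radii must be >= 0")
        if self.min_object_area_px < 0:
            raise ValueError("min_object_area_px must be >= 0")


@dataclass
class OrganismMask:
    mask: np.ndarray  # boolean, True = organism
    segment_count: int
    area_px: int
    z_index: int = 0


def _border_band(img: np.ndarray, width: int) -> np.ndarray:
    w = max(1, min(width, min(img.shape) // 2))
    edge = np.concatenate([
        img[:w, :].ravel(), img[-w:, :].ravel(),
        img[w:-w, :w].ravel(), img[w:-w, -w:].ravel(),
    ])
    return edge


def segment_organism(
    tl: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    z_index: int = 0,
) -> OrganismMask:
    """Segment the organism from one transmitted-light plane.

    A constant (zero-contrast) image yields an empty mask with
    segment_count 0 rather than an error.
    """
    img = np.asarray(tl, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("transmitted-light image contains non-finite values")

    smoothed = (
        ndimage.gaussian_filter(img, params.smoothing_sigma_px)
        if params.smoothing_sigma_px > 0 else img
    )
    band = _border_band(smoothed, params.border_band_px)
    background = float(np.median(band))

    if params.polarity == "dark_object":
        diff = np.clip(background - smoothed, 0.0, None)
    elif params.polarity == "bright_object":
        diff = np.clip(smoothed - background, 0.0, None)
    else:
        diff = np.abs(smoothed - background)

    empty = OrganismMask(
        mask=np.zeros(img.shape, dtype=bool), segment_count=0, area_px=0,
        z_index=z_index,
    )
    if np.ptp(diff) == 0:
        return empty
    try:
        threshold = filters.threshold_otsu(diff)
    except ValueError:  # single-valued image
        return empty

    # robust noise scale of the border band; reject thresholds that sit
    # inside the noise distribution (background-only well)
    band_diff = np.abs(band - background)
    noise_scale = 1.4826 * float(np.median(np.abs(band_diff - np.median(band_diff))))
    if threshold <= params.min_contrast_snr * max(noise_scale, 1e-12):
        return empty

    mask = diff > threshold
    if params.closing_radius_px > 0:
        mask = ndimage.binary_closing(
            mask, structure=morphology.disk(params.closing_radius_px)
        )
    if params.fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    labels, count = measure.label(mask, connectivity=2, return_num=True)
    if params.min_object_area_px > 0 and count:
        areas = np.bincount(labels.ravel())[1:]
        keep = np.flatnonzero(areas >= params.min_object_area_px) + 1
        mask = np.isin(labels, keep)
        labels, count = measure.label(mask, connectivity=2, return_num=True)
    return OrganismMask(
        mask=mask, segment_count=int(count), area_px=int(mask.sum()),
        z_index=z_index,
    )


def z_level_correct(mask: OrganismMask) -> bool:
    """True iff exactly one organism was found at this z-level.

    Zero segments means the outline was not found; more than one means an
    extra animal or an artifact was labelled — both invalidate the layer.
    """
    return mask.segment_count == 1
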