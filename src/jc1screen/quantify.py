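"""Masked fluorescence quantification and QC aggregation.

Applies the transmitted-light organism mask to the Cy3 (J-aggregate, red)
and FITC (monomer, green) channels, excludes saturated pixels, computes the
per-z-level red/green ratio, and averages over z-levels per individual with
the QC exclusion rules:

* a z-level is correct only if exactly one segment was found and usable
  (non-saturated, in-mask) pixels remain with a positive FITC mean;
* Cy3 pixels at or above the saturation threshold (default 65000) are
  excluded from BOTH channel means, keeping the ratio's pixel set paired;
* an individual is excluded entirely when more than 50% of its z-levels
  are incorrect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .segmentation import OrganismMask, z_level_correct

__all__ = [
    "ZLevelMeasurement", "IndividualResult", "masked_channel_means",
    "red_green_ratio", "aggregate_individual",
]

SATURATION_THRESHOLD = 65000
MAX_INCORRECT_Z_FRACTION = 0.5


@dataclass(frozen=True)
class ZLevelMeasurement:
    well_id: str
    z_index: int
    area_px: int
    mean_cy3: float
    mean_fitc: float
    n_saturated_px: int
    segment_count: int
    z_correct: bool
    ratio: float  # NaN when undefined


@dataclass(frozen=True)
class IndividualResult:
    well_id: str
    ratio: float  # z-averaged red/green ratio; NaN when QC-failed
    n_z_total: int
    n_z_correct: int
    qc_pass: bool
    normalized_ratio: Optional[float] = None


def masked_channel_means(
    mask: OrganismMask,
    cy3: np.ndarray,
    fitc: np.ndarray,
    saturation_threshold: float = SATURATION_THRESHOLD,
    well_id: str = "",
    exclude_fitc_saturation: bool = False,
) -> ZLevelMeasurement:
    """Mean Cy3/FITC intensity inside the mask with paired saturation exclusion.

    Pixels whose Cy3 value is at or above ``saturation_threshold`` are
    removed from both channels before averaging.  If every mask pixel is
    saturated, the means are undefined and the layer is marked incorrect.
    ``exclude_fitc_saturation`` additionally drops FITC-saturated pixels
    (off by default: only the Cy3 channel is thresholded).
    """
    cy3 = np.asarray(cy3)
    fitc = np.asarray(fitc)
    if cy3.shape != mask.mask.shape or fitc.shape != mask.mask.shape:
        raise ValueError("fluorescence images must match the mask dimensions")
    if not (0 < saturation_threshold <= 65535):
        raise ValueError("saturation threshold must be in (0, 65535]")

    inside = mask.mask
    saturated = inside & (cy3 >= saturation_threshold)
    if exclude_fitc_saturation:
        saturated |= inside & (fitc >= saturation_threshold)
    usable = inside & ~saturated
    n_saturated = int(saturated.sum())

    if usable.sum() == 0:
        mean_cy3 = mean_fitc = float("nan")
        correct = False
    else:
        mean_cy3 = float(cy3[usable].mean())
        mean_fitc = float(fitc[usable].mean())
        correct = z_level_correct(mask) and mean_fitc > 0

    ratio = mean_cy3 / mean_fitc if correct else float("nan")
    return ZLevelMeasurement(
        well_id=well_id, z_index=mask.z_index, area_px=mask.area_px,
        mean_cy3=mean_cy3, mean_fitc=mean_fitc, n_saturated_px=n_saturated,
        segment_count=mask.segment_count, z_correct=correct, ratio=ratio,
    )


def red_green_ratio(meas: ZLevelMeasurement) -> float:
    """Red/green (Cy3/FITC) ratio of one z-level measurement."""
    if not (math.isfinite(meas.mean_cy3) and math.isfinite(meas.mean_fitc)):
        raise ValueError("channel means are undefined")
    if meas.mean_fitc <= 0:
        raise ValueError("FITC mean must be positive for a defined ratio")
    return meas.mean_cy3 / meas.mean_fitc


def aggregate_individual(
    z_measurements: Sequence[ZLevelMeasurement],
    max_incorrect_fraction: float = MAX_INCORRECT_Z_FRACTION,
) -> IndividualResult:
    """Average z-level ratios into one per-individual result with QC status.

    The individual passes QC when the fraction of incorrect z-levels does
    not exceed ``max_incorrect_fraction`` (strictly more than 50% incorrect
    excludes) and at least one correct layer exists.  The ratio is the
    arithmetic mean over correct layers only.
    """
    meas = list(z_measurements)
    if not meas:
        raise ValueError("no z-level measurements supplied")
    wells = {m.well_id for m in meas}
    if len(wells) > 1:
        raise ValueError(f"measurements span multiple wells: {sorted(wells)}")

    correct = [m.ratio for m in meas if m.z_correct and math.isfinite(m.ratio)]
    n_total = len(meas)
    n_correct = len(correct)
    incorrect_fraction = (n_total - n_correct) / n_total
    qc_pass = n_correct >= 1 and incorrect_fraction <= max_incorrect_fraction
    ratio = float(np.mean(correct)) if qc_pass else float("nan")
    return IndividualResult(
        well_id=meas[0].well_id, ratio=ratio, n_z_total=n_total,
        n_z_correct=n_correct, qc_pass=qc_pass,
    )
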