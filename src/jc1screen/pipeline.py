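"""Pipeline configuration and orchestration.

Glue between the modules: analyze a directory of well stacks into
measurement tables, and fit the constrained log-logistic models per
compound, endpoint and timepoint into a report table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import doseresponse as dr
from . import io_plate, quantify
from .segmentation import SegmentationParams, segment_organism

logger = logging.getLogger(__name__)

FIT_REPORT_COLUMNS = [
    "compound", "endpoint", "timepoint_h", "family", "b", "c", "d", "e",
    "ec10", "ec10_lo", "ec10_hi", "ec50", "ec50_lo", "ec50_hi",
    "converged", "n_points", "ci_overlap_with_other_endpoint",
]


@dataclass
class PipelineConfig:
    """Defaults reproduce the screening protocol constants: Cy3 saturation
    threshold 65000, exclusion above 50% incorrect z-levels, EC levels
    {10, 50}, alpha 0.05."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    saturation_threshold: float = 65000.0
    exclude_fitc_saturation: bool = False
    max_incorrect_z_fraction: float = 0.5
    ec_levels: tuple = (10.0, 50.0)
    ci_method: str = "delta_original"
    immobilization_fit: str = "binomial_ml"
    alpha: float = 0.05
    jc1_floor: float | None = None  # used when no dead-control wells exist
    debug_masks: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        seg = SegmentationParams(**raw.pop("segmentation", {}))
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "ec_levels" in known:
            known["ec_levels"] = tuple(known["ec_levels"])
        return cls(segmentation=seg, **known)

    def apply_overrides(self, overrides: dict) -> "PipelineConfig":
        seg_over = {
            k.split(".", 1)[1]: v for k, v in overrides.items()
            if k.startswith("segmentation.")
        }
        top = {k: v for k, v in overrides.items() if "." not in k}
        seg = replace(self.segmentation, **seg_over) if seg_over else self.segmentation
        return replace(self, segmentation=seg, **top)


def analyze_plate(image_dir, layout: io_plate.PlateLayout,
                  config: PipelineConfig | None = None,
                  mask_dir=None):
    """Segment and quantify every discoverable well stack.

    Returns ``(z_rows, individuals)``.  QC exclusions are logged with the
    well id and reason (segment count 0, segment count > 1, or more than
    50% incorrect z-levels).
    """
    config = config or PipelineConfig()
    stacks = io_plate.discover_well_stacks(image_dir)
    if not stacks:
        raise FileNotFoundError(f"no well stacks found in {image_dir}")
    known_wells = {e.well_id for e in layout.entries}

    z_rows, individuals = [], []
    for well_id, files in stacks.items():
        if well_id not in known_wells:
            logger.warning("well %s has images but no layout entry; skipped",
                           well_id)
            continue
        stack = io_plate.read_well_stack(files)
        meas = []
        for iz, plane in enumerate(stack.z_levels, start=1):
            mask = segment_organism(plane.tl, config.segmentation, z_index=iz)
            if mask_dir is not None:
                Path(mask_dir).mkdir(parents=True, exist_ok=True)
                tifffile.imwrite(
                    Path(mask_dir) / f"{well_id}_z{iz}_MASK.tif",
                    mask.mask.astype(np.uint8) * 255,
                )
            meas.append(quantify.masked_channel_means(
                mask, plane.cy3, plane.fitc,
                saturation_threshold=config.saturation_threshold,
                well_id=well_id,
                exclude_fitc_saturation=config.exclude_fitc_saturation,
            ))
        ind = quantify.aggregate_individual(
            meas, max_incorrect_fraction=config.max_incorrect_z_fraction
        )
        if not ind.qc_pass:
            counts = [m.segment_count for m in meas]
            if all(c == 0 for c in counts):
                reason = "segment_count == 0"
            elif any(c > 1 for c in counts):
                reason = "segment_count > 1"
            else:
                reason = (
                    f"more than {config.max_incorrect_z_fraction:.0%} "
                    "of z-levels incorrect"
                )
            logger.info("QC exclusion: well %s (%s)", well_id, reason)
        z_rows.extend(meas)
        individuals.append(ind)
    return z_rows, individuals


def _ci_overlap(a_lo, a_hi, b_lo, b_hi) -> bool:
    return a_lo <= b_hi and b_lo <= a_hi


def fit_report(individuals, immobilization, layout: io_plate.PlateLayout,
               config: PipelineConfig | None = None) -> pd.DataFrame:
    """Fit per compound x timepoint: LL4 on normalized JC-1 ratios and LL2
    on immobilization counts; report ECx with 95% CIs and the CI-overlap
    flag between the two endpoints."""
    config = config or PipelineConfig()
    rows = []

    by_well = {e.well_id: e for e in layout.entries}
    if individuals:
        normalized = dr.normalize_to_control(individuals, layout)
        dead = [
            ind for ind in normalized
            if by_well[ind.well_id].role == "dead_control"
        ]
        if dead:
            floor = dr.dead_control_floor(dead)
        elif config.jc1_floor is not None:
            floor = config.jc1_floor
        else:
            raise ValueError(
                "JC-1 lower limit unavailable: the plate has no dead-control "
                "wells and config.jc1_floor is not set"
            )
        treated = [
            ind for ind in normalized
            if by_well[ind.well_id].role == "treatment"
        ]
        controls = [
            ind for ind in normalized
            if by_well[ind.well_id].role in ("control", "solvent_control")
        ]
        points = dr.aggregate_replicate_means(treated + controls, layout)
        for (compound, tp) in sorted({(p.compound, p.timepoint_h) for p in points}):
            sub = [p for p in points
                   if p.compound == compound and p.timepoint_h == tp]
            rows.append(_fit_row_jc1(sub, floor, compound, tp, config))

    if immobilization:
        for (tp,) in sorted({(r.timepoint_h,) for r in immobilization}):
            recs = [r for r in immobilization if r.timepoint_h == tp]
            compound = layout.entries[0].compound if layout.entries else ""
            rows.append(_fit_row_immobilization(recs, compound, tp, config))

    df = pd.DataFrame(rows, columns=FIT_REPORT_COLUMNS)
    df["ci_overlap_with_other_endpoint"] = df[
        "ci_overlap_with_other_endpoint"].astype(object)
    # flag EC50 CI overlap between endpoints sharing compound and timepoint
    for (compound, tp), grp in df.groupby(["compound", "timepoint_h"]):
        if set(grp["endpoint"]) >= {"jc1", "immobilization"}:
            jc1 = grp[grp.endpoint == "jc1"].iloc[0]
            imm = grp[grp.endpoint == "immobilization"].iloc[0]
            flag = _ci_overlap(jc1.ec50_lo, jc1.ec50_hi,
                               imm.ec50_lo, imm.ec50_hi)
            df.loc[grp.index, "ci_overlap_with_other_endpoint"] = flag
    return df


def _ec_pair(fit, p, config):
    try:
        est = dr.ec_x(fit, p, ci_method=config.ci_method)
        return est.value, est.ci_low, est.ci_high
    except ValueError:
        return np.nan, np.nan, np.nan


def _fit_row_jc1(points, floor, compound, tp, config):
    try:
        fit = dr.fit_ll4(points, c_fixed=floor)
    except ValueError as exc:
        logger.warning("JC-1 fit failed for %s at %g h: %s", compound, tp, exc)
        return dict.fromkeys(FIT_REPORT_COLUMNS, np.nan) | {
            "compound": compound, "endpoint": "jc1", "timepoint_h": tp,
            "family": "LL4", "converged": False, "n_points": len(points),
            "ci_overlap_with_other_endpoint": np.nan,
        }
    ec10 = _ec_pair(fit, 10.0, config)
    ec50 = _ec_pair(fit, 50.0, config)
    return {
        "compound": compound, "endpoint": "jc1", "timepoint_h": tp,
        "family": "LL4", "b": fit.b, "c": fit.c, "d": fit.d, "e": fit.e,
        "ec10": ec10[0], "ec10_lo": ec10[1], "ec10_hi": ec10[2],
        "ec50": ec50[0], "ec50_lo": ec50[1], "ec50_hi": ec50[2],
        "converged": fit.converged, "n_points": fit.n_points,
        "ci_overlap_with_other_endpoint": np.nan,
    }


def _fit_row_immobilization(recs, compound, tp, config):
    try:
        fit = dr.fit_ll2(recs)
    except ValueError as exc:
        logger.warning("immobilization fit failed at %g h: %s", tp, exc)
        return dict.fromkeys(FIT_REPORT_COLUMNS, np.nan) | {
            "compound": compound, "endpoint": "immobilization",
            "timepoint_h": tp, "family": "LL2", "converged": False,
            "n_points": len(recs),
            "ci_overlap_with_other_endpoint": np.nan,
        }
    ec10 = _ec_pair(fit, 10.0, config)
    ec50 = _ec_pair(fit, 50.0, config)
    return {
        "compound": compound, "endpoint": "immobilization", "timepoint_h": tp,
        "family": "LL2", "b": fit.b, "c": fit.c, "d": fit.d, "e": fit.e,
        "ec10": ec10[0], "ec10_lo": ec10[1], "ec10_hi": ec10[2],
        "ec50": ec50[0], "ec50_lo": ec50[1], "ec50_hi": ec50[2],
        "converged": fit.converged, "n_points": fit.n_points,
        "ci_overlap_with_other_endpoint": np.nan,
    }
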