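"""Plate metadata and image-stack I/O.

Reads the plate-layout and immobilization CSVs, discovers and loads
per-well TIFF z-stacks, and writes/reads the tabular measurement output.

File naming convention for image stacks: ``<well>_z<k>_<channel>.tif`` with
channel in {TL, CY3, FITC} and z 1-based.  Layout CSV header:
``well_id,compound,concentration,unit,role,experiment_id,timepoint_h,n_individuals``.
Immobilization CSV header:
``well_group,concentration,unit,n_exposed,n_immobile,experiment_id,timepoint_h``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

ROLES = ("control", "solvent_control", "treatment", "dead_control")
ZERO_CONC_ROLES = ("control", "solvent_control", "dead_control")

LAYOUT_COLUMNS = [
    "well_id", "compound", "concentration", "unit", "role",
    "experiment_id", "timepoint_h", "n_individuals",
]
IMMOBILIZATION_COLUMNS = [
    "well_group", "concentration", "unit", "n_exposed", "n_immobile",
    "experiment_id", "timepoint_h",
]
ZLEVEL_COLUMNS = [
    "well_id", "z", "area_px", "mean_cy3", "mean_fitc",
    "n_saturated_px", "segment_count", "z_correct", "ratio",
]
INDIVIDUAL_COLUMNS = [
    "well_id", "ratio", "n_z_total", "n_z_correct", "qc_pass",
    "normalized_ratio",
]

_STACK_RE = re.compile(
    r"^(?P<well>.+)_z(?P<z>\d+)_(?P<ch>TL|CY3|FITC)\.tiff?$"
)
CHANNELS = ("TL", "CY3", "FITC")


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class StackError(ValueError):
    """An image stack is incomplete or inconsistent."""


@dataclass(frozen=True)
class PlateEntry:
    well_id: str
    compound: str
    concentration: float
    unit: str
    role: str
    experiment_id: str
    timepoint_h: float
    n_individuals: int


@dataclass(frozen=True)
class PlateLayout:
    entries: tuple[PlateEntry, ...]

    def __len__(self):
        return len(self.entries)

    def by_role(self, role: str) -> list[PlateEntry]:
        return [e for e in self.entries if e.role == role]


@dataclass(frozen=True)
class ImmobilizationRecord:
    well_group: str
    concentration: float
    unit: str
    n_exposed: int
    n_immobile: int
    experiment_id: str
    timepoint_h: float

    def __post_init__(self):
        if not (0 <= self.n_immobile <= self.n_exposed):
            raise ValueError(
                f"{self.well_group}: n_immobile must be within "
                f"[0, n_exposed={self.n_exposed}]"
            )


@dataclass
class ZPlane:
    tl: np.ndarray
    cy3: np.ndarray
    fitc: np.ndarray


@dataclass
class WellStack:
    """Ordered z-stack of co-registered TL/Cy3/FITC images for one well."""

    well_id: str
    z_levels: list[ZPlane]
    z_spacing_um: float = 15.0
    pixel_size_um: float = 1.72

    def __post_init__(self):
        if not self.z_levels:
            raise StackError(f"{self.well_id}: stack has no z-levels")
        shape = self.z_levels[0].tl.shape
        for i, zp in enumerate(self.z_levels):
            for ch in (zp.tl, zp.cy3, zp.fitc):
                if ch.shape != shape:
                    raise StackError(
                        f"{self.well_id}: image dimensions differ at z={i + 1}"
                    )


# ---------------------------------------------------------------------------
# metadata


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {', '.join(missing)}")


def read_plate_layout(path) -> PlateLayout:
    """Read and validate a plate-layout CSV.

    Rows with an unknown role are rejected; duplicate wells within an
    (experiment, timepoint) block raise; treatment rows at concentration 0
    are accepted with a warning (kept distinct from the control group).
    """
    df = pd.read_csv(path, dtype={"well_id": str, "experiment_id": str})
    _require_columns(df, LAYOUT_COLUMNS, "plate layout")

    bad_roles = sorted(set(df["role"]) - set(ROLES))
    if bad_roles:
        raise SchemaError(f"plate layout: unknown role(s) {bad_roles}")

    dup = df.duplicated(subset=["well_id", "experiment_id", "timepoint_h"])
    if dup.any():
        wells = df.loc[dup, "well_id"].tolist()
        raise ValueError(f"duplicate well(s) within experiment/timepoint: {wells}")

    entries = []
    for row in df.itertuples(index=False):
        conc = float(row.concentration)
        if conc < 0:
            raise ValueError(f"well {row.well_id}: negative concentration")
        if row.role in ZERO_CONC_ROLES and conc != 0:
            raise ValueError(
                f"well {row.well_id}: role {row.role} requires concentration 0"
            )
        if row.role == "treatment" and conc == 0:
            logger.warning(
                "well %s: treatment at concentration 0 (kept as treatment, "
                "not pooled into controls)", row.well_id,
            )
        entries.append(PlateEntry(
            well_id=str(row.well_id), compound=str(row.compound),
            concentration=conc, unit=str(row.unit), role=str(row.role),
            experiment_id=str(row.experiment_id),
            timepoint_h=float(row.timepoint_h),
            n_individuals=int(row.n_individuals),
        ))
    return PlateLayout(entries=tuple(entries))


def write_plate_layout(layout: PlateLayout, path) -> None:
    pd.DataFrame([e.__dict__ for e in layout.entries],
                 columns=LAYOUT_COLUMNS).to_csv(path, index=False)


def read_immobilization(path) -> list[ImmobilizationRecord]:
    df = pd.read_csv(path, dtype={"well_group": str, "experiment_id": str})
    _require_columns(df, IMMOBILIZATION_COLUMNS, "immobilization table")
    return [
        ImmobilizationRecord(
            well_group=str(r.well_group), concentration=float(r.concentration),
            unit=str(r.unit), n_exposed=int(r.n_exposed),
            n_immobile=int(r.n_immobile), experiment_id=str(r.experiment_id),
            timepoint_h=float(r.timepoint_h),
        )
        for r in df.itertuples(index=False)
    ]


def write_immobilization(records, path) -> None:
    pd.DataFrame([r.__dict__ for r in records],
                 columns=IMMOBILIZATION_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# image stacks


def discover_well_stacks(directory, naming: str = "default") -> dict[str, list[Path]]:
    """Group TIFF files by well into z- and channel-ordered file lists.

    Returns ``{well_id: [z1 TL, z1 CY3, z1 FITC, z2 TL, ...]}`` with z
    ascending.  Raises StackError naming any well whose z-levels do not all
    have the full TL/CY3/FITC channel set.
    """
    if naming != "default":
        raise ValueError(f"unknown naming convention {naming!r}")
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"{directory} is not a directory")

    wells: dict[str, dict[int, dict[str, Path]]] = {}
    for f in sorted(directory.iterdir()):
        m = _STACK_RE.match(f.name)
        if not m:
            continue
        wells.setdefault(m["well"], {}).setdefault(int(m["z"]), {})[m["ch"]] = f

    incomplete = [
        well for well, zmap in wells.items()
        if any(set(chs) != set(CHANNELS) for chs in zmap.values())
    ]
    if incomplete:
        raise StackError(
            f"incomplete stack(s), missing channel files: {sorted(incomplete)}"
        )
    return {
        well: [zmap[z][ch] for z in sorted(zmap) for ch in CHANNELS]
        for well, zmap in sorted(wells.items())
    }


def _load_plane(path: Path) -> np.ndarray:
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise StackError(f"{path.name}: expected a single 2D plane")
    if img.dtype == np.uint8:
        logger.warning("%s: 8-bit image rescaled to the 16-bit range", path.name)
        img = img.astype(np.uint16) * 257  # 255 -> 65535
    elif img.dtype != np.uint16:
        raise StackError(f"{path.name}: expected 8- or 16-bit grayscale")
    return img


def read_well_stack(
    files: Sequence, z_spacing_um: float = 15.0, pixel_size_um: float = 1.72
) -> WellStack:
    """Load an ordered file list (as produced by discover_well_stacks)."""
    files = [Path(f) for f in files]
    if not files or len(files) % 3:
        raise StackError("file list must hold TL/CY3/FITC triplets")
    planes: dict[int, dict[str, np.ndarray]] = {}
    well_id = None
    for f in files:
        m = _STACK_RE.match(f.name)
        if not m:
            raise StackError(f"{f.name}: does not match naming convention")
        well_id = well_id or m["well"]
        planes.setdefault(int(m["z"]), {})[m["ch"]] = _load_plane(f)
    z_levels = [
        ZPlane(tl=chs["TL"], cy3=chs["CY3"], fitc=chs["FITC"])
        for z, chs in sorted(planes.items())
    ]
    return WellStack(well_id=well_id, z_levels=z_levels,
                     z_spacing_um=z_spacing_um, pixel_size_um=pixel_size_um)


# ---------------------------------------------------------------------------
# measurement tables


def write_measurements(z_rows, individuals, z_path, individual_path) -> None:
    """Write per-z-level and per-individual measurement CSVs."""
    zdf = pd.DataFrame(
        [
            {
                "well_id": m.well_id, "z": m.z_index, "area_px": m.area_px,
                "mean_cy3": m.mean_cy3, "mean_fitc": m.mean_fitc,
                "n_saturated_px": m.n_saturated_px,
                "segment_count": m.segment_count,
                "z_correct": m.z_correct, "ratio": m.ratio,
            }
            for m in z_rows
        ],
        columns=ZLEVEL_COLUMNS,
    )
    zdf.to_csv(z_path, index=False)
    idf = pd.DataFrame(
        [
            {
                "well_id": r.well_id, "ratio": r.ratio,
                "n_z_total": r.n_z_total, "n_z_correct": r.n_z_correct,
                "qc_pass": r.qc_pass,
                "normalized_ratio": (
                    np.nan if r.normalized_ratio is None else r.normalized_ratio
                ),
            }
            for r in individuals
        ],
        columns=INDIVIDUAL_COLUMNS,
    )
    idf.to_csv(individual_path, index=False)


def read_measurements(z_path, individual_path):
    """Read back measurement CSVs (round-trips numeric fields losslessly)."""
    from .quantify import IndividualResult, ZLevelMeasurement

    zdf = pd.read_csv(z_path, dtype={"well_id": str})
    _require_columns(zdf, ZLEVEL_COLUMNS, "z-level measurements")
    z_rows = [
        ZLevelMeasurement(
            well_id=r.well_id, z_index=int(r.z), area_px=int(r.area_px),
            mean_cy3=float(r.mean_cy3), mean_fitc=float(r.mean_fitc),
            n_saturated_px=int(r.n_saturated_px),
            segment_count=int(r.segment_count), z_correct=bool(r.z_correct),
            ratio=float(r.ratio),
        )
        for r in zdf.itertuples(index=False)
    ]
    idf = pd.read_csv(individual_path, dtype={"well_id": str})
    _require_columns(idf, INDIVIDUAL_COLUMNS, "individual measurements")
    individuals = [
        IndividualResult(
            well_id=r.well_id, ratio=float(r.ratio),
            n_z_total=int(r.n_z_total), n_z_correct=int(r.n_z_correct),
            qc_pass=bool(r.qc_pass),
            normalized_ratio=(
                None if pd.isna(r.normalized_ratio) else float(r.normalized_ratio)
            ),
        )
        for r in idf.itertuples(index=False)
    ]
    return z_rows, individuals
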