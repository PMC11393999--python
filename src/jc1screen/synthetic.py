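"""Synthetic plate generator: tabular dose-response data and phantom images.

The raw screening images cannot be redistributed, so validation runs
against plates this module fabricates with known ground truth:

* ``simulate_response_tables`` draws replicate-mean JC-1 ratios from a
  four-parameter log-logistic curve with Gaussian noise and immobilization
  counts from a binomial with LL2 success probability — the tabular study
  design (concentration series, 5 individuals per well group, 3 independent
  experiments).
* ``generate_well_stack`` renders a full TL/Cy3/FITC z-stack for one well:
  a darker two-ellipse organism phantom on a bright transmitted-light
  background, diffuse FITC monomer signal on the silhouette, punctate Cy3
  J-aggregate signal scaled so the in-mask red/green ratio equals the
  log-logistic truth at that dose, plus optional artifacts (saturated
  patches, extra-organismal dye aggregates, empty and double-occupancy
  wells).
* ``generate_plate`` writes a whole plate in the io_plate naming
  convention together with a JSON truth manifest.

Noise is Poisson shot noise plus Gaussian read noise per channel.  All
outputs are reproducible from the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.morphology import disk as morphology_disk

from .doseresponse import ResponsePoint, ll2_response, ll4_response
from .io_plate import (ImmobilizationRecord, PlateEntry, PlateLayout,
                       write_immobilization, write_plate_layout)

__all__ = [
    "SimulationTruth", "PhantomParams", "ArtifactRates",
    "simulate_response_tables", "generate_well_stack", "generate_plate",
    "make_layout", "CCCP_CONCENTRATIONS_UG_L",
]

# CCCP concentration series of the model-compound experiments (μg/L)
CCCP_CONCENTRATIONS_UG_L = (0.5, 5.0, 25.0, 50.0, 250.0, 500.0, 2500.0)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth curves and design for one simulated exposure experiment.

    Defaults mirror the screening design: the CCCP concentration series,
    five individuals per well group, three independent experiments, a
    falling JC-1 ratio curve (b=2, floor 0.2, top 1, EC50 100) and a rising
    immobilization curve (b=-4, EC50 500).
    """

    ll4: tuple = (2.0, 0.2, 1.0, 100.0)  # (b, c, d, e), normalized ratio
    ll2: tuple = (-4.0, 500.0)           # (b, e), immobile fraction
    concentrations: tuple = CCCP_CONCENTRATIONS_UG_L
    n_individuals_per_conc: int = 5
    n_experiments: int = 3
    noise_sd: float = 0.05
    seed: int = 0
    compound: str = "CCCP"
    unit: str = "ug/L"
    timepoint_h: float = 2.0

    def __post_init__(self):
        if self.ll4[3] <= 0 or self.ll2[1] <= 0:
            raise ValueError("inflection concentrations must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(set(self.concentrations)) != len(self.concentrations) or any(
            c < 0 for c in self.concentrations
        ):
            raise ValueError("concentrations must be distinct and >= 0")


@dataclass(frozen=True)
class ArtifactRates:
    saturated_patch: float = 0.0
    external_aggregate: float = 0.0
    empty_well: float = 0.0
    double_occupancy: float = 0.0

    def __post_init__(self):
        for name, p in asdict(self).items():
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be a probability")


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and intensity model of the rendered well images."""

    image_size_px: tuple = (256, 256)
    body_axes_px: tuple = (36.0, 22.0)   # semi-axes of the body ellipse
    tl_background: float = 30000.0
    tl_contrast: float = 12000.0         # organism darker than background
    cy3_puncta_density: float = 2.0      # aggregates per organism pixel
    cy3_puncta_intensity: float = 20000.0
    cy3_background: float = 200.0
    fitc_diffuse_intensity: float = 8000.0
    fitc_background: float = 300.0
    control_raw_ratio: float = 2.0       # red/green of a healthy control
    read_noise_sd: float = 120.0
    shot_noise_gain: float = 0.05        # photons per intensity unit
    z_attenuation: float = 0.4           # fractional falloff toward body center
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    z_levels: int = 10

    def __post_init__(self):
        if self.z_levels < 1:
            raise ValueError("z_levels must be >= 1")
        if 2 * self.body_axes_px[0] >= min(self.image_size_px):
            raise ValueError("organism larger than the image field")


# ---------------------------------------------------------------------------
# tabular simulation


def simulate_response_tables(truth: SimulationTruth):
    """Draw (jc1 ResponsePoints, ImmobilizationRecords) from the truth curves.

    Each JC-1 point is a replicate mean: LL4(conc) plus Gaussian noise of
    sd ``noise_sd / sqrt(n_individuals)``.  Each immobilization record draws
    counts from Binomial(n_individuals, LL2(conc)).
    """
    rng = np.random.default_rng(truth.seed)
    b4, c4, d4, e4 = truth.ll4
    b2, e2 = truth.ll2
    n = truth.n_individuals_per_conc
    points, records = [], []
    for i_exp in range(1, truth.n_experiments + 1):
        exp_id = f"E{i_exp}"
        for conc in truth.concentrations:
            mean = ll4_response(conc, b4, c4, d4, e4)
            noise = rng.normal(0.0, truth.noise_sd / math.sqrt(n))
            points.append(ResponsePoint(
                concentration=conc, response=mean + noise,
                experiment_id=exp_id, n_individuals=n, endpoint="jc1",
                compound=truth.compound, timepoint_h=truth.timepoint_h,
            ))
            p = ll2_response(conc, b2, e2)
            records.append(ImmobilizationRecord(
                well_group=f"{exp_id}_{conc:g}", concentration=conc,
                unit=truth.unit, n_exposed=n,
                n_immobile=int(rng.binomial(n, p)),
                experiment_id=exp_id, timepoint_h=truth.timepoint_h,
            ))
    return points, records


# ---------------------------------------------------------------------------
# image phantoms


def _ellipse_mask(shape, center, axes, angle_rad):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    dy, dx = yy - center[0], xx - center[1]
    ca, sa = math.cos(angle_rad), math.sin(angle_rad)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _organism_silhouette(shape, rng, phantom: PhantomParams):
    """Two-ellipse body+head composite at a random pose near the center."""
    a, b = phantom.body_axes_px
    margin = a + 10
    cy = rng.uniform(margin, shape[0] - margin)
    cx = rng.uniform(margin, shape[1] - margin)
    theta = rng.uniform(0, math.pi)
    body = _ellipse_mask(shape, (cy, cx), (a, b), theta)
    # head: smaller ellipse offset along the major axis
    hy = cy + 0.9 * a * math.sin(theta)
    hx = cx + 0.9 * a * math.cos(theta)
    head = _ellipse_mask(shape, (hy, hx), (0.45 * a, 0.45 * b), theta)
    return body | head


def _camera_noise(img, rng, phantom: PhantomParams):
    gain = phantom.shot_noise_gain
    if gain > 0:
        img = rng.poisson(np.clip(img, 0, None) * gain) / gain
    if phantom.read_noise_sd > 0:
        img = img + rng.normal(0.0, phantom.read_noise_sd, size=img.shape)
    return img


def _quantize(img):
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


def generate_well_stack(
    dose: float,
    truth: SimulationTruth,
    phantom: PhantomParams,
    rng: np.random.Generator,
    role: str = "treatment",
):
    """Render one well's TL/Cy3/FITC z-stack plus its ground truth.

    Returns ``(planes, info)`` where ``planes`` is a list of
    ``(tl, cy3, fitc)`` uint16 arrays (one per z-level) and ``info`` holds
    the silhouette mask, the intended raw red/green ratio, occupancy, and
    injected artifact flags.  Dead-control wells are rendered at the LL4
    floor ratio regardless of dose.
    """
    shape = tuple(phantom.image_size_px)
    rates = phantom.artifact_rates
    b4, c4, d4, e4 = truth.ll4

    if role == "dead_control":
        normalized = c4
    else:
        normalized = ll4_response(dose, b4, c4, d4, e4)
    raw_ratio = normalized * phantom.control_raw_ratio

    occupancy = 1
    if rng.random() < rates.empty_well:
        occupancy = 0
    elif rng.random() < rates.double_occupancy:
        occupancy = 2

    silhouette = np.zeros(shape, dtype=bool)
    for _ in range(occupancy):
        body = _organism_silhouette(shape, rng, phantom)
        if silhouette.any():
            # second animal must stay a separate connected component
            gap = ndimage.binary_dilation(silhouette, morphology_disk(6))
            for _ in range(50):
                if not (body & gap).any():
                    break
                body = _organism_silhouette(shape, rng, phantom)
        silhouette |= body

    # distance-from-boundary proxy for the translucent body center
    if silhouette.any():
        depth = ndimage.distance_transform_edt(silhouette)
        depth = depth / depth.max() if depth.max() > 0 else depth
    else:
        depth = np.zeros(shape)

    saturate = rng.random() < rates.saturated_patch and silhouette.any()
    aggregate = rng.random() < rates.external_aggregate

    planes = []
    for iz in range(phantom.z_levels):
        # deeper z-levels image closer to the translucent body center
        m_z = 1.0 - phantom.z_attenuation * (
            iz / max(phantom.z_levels - 1, 1)
        ) * depth

        tl = np.full(shape, phantom.tl_background, dtype=float)
        tl[silhouette] -= phantom.tl_contrast

        fitc = np.full(shape, phantom.fitc_background, dtype=float)
        fitc_sig = phantom.fitc_diffuse_intensity * m_z
        fitc[silhouette] += fitc_sig[silhouette]

        cy3 = np.full(shape, phantom.cy3_background, dtype=float)
        if silhouette.any():
            target_cy3_mean = raw_ratio * float(fitc[silhouette].mean())
            excess = max(target_cy3_mean - phantom.cy3_background, 0.0)
            area = int(silhouette.sum())
            sigma = 1.5
            n_puncta = max(rng.poisson(phantom.cy3_puncta_density * area), 1)
            ys, xs = np.nonzero(silhouette)
            pick = rng.integers(0, ys.size, size=n_puncta)
            spots = np.zeros(shape)
            np.add.at(spots, (ys[pick], xs[pick]),
                      phantom.cy3_puncta_intensity)
            # normalized convolution keeps the texture stationary up to the
            # silhouette border (no edge falloff that would bias the ratio
            # when saturated patches are excluded)
            nrm = ndimage.gaussian_filter(silhouette.astype(float), sigma)
            spots = ndimage.gaussian_filter(spots, sigma)
            spots = np.where(silhouette,
                             spots / np.maximum(nrm, 1e-6), 0.0) * m_z
            # scale puncta so the in-mask mean Cy3 hits the target ratio
            spot_mean = float(spots[silhouette].mean())
            if excess > 0 and spot_mean > 0:
                spots *= excess / spot_mean
            cy3 += spots

        if aggregate:
            # extra-organismal dye aggregate: bright blob outside the body,
            # with a small (sub-threshold) TL shadow
            for _ in range(20):
                ay = rng.uniform(10, shape[0] - 10)
                ax = rng.uniform(10, shape[1] - 10)
                blob = _ellipse_mask(shape, (ay, ax), (5.0, 4.0),
                                     rng.uniform(0, math.pi))
                if not (blob & silhouette).any():
                    cy3[blob] += 30000.0
                    fitc[blob] += 10000.0
                    tl[blob] -= 0.5 * phantom.tl_contrast
                    break

        tl = _camera_noise(tl, rng, phantom)
        cy3 = _camera_noise(cy3, rng, phantom)
        fitc = _camera_noise(fitc, rng, phantom)

        if saturate:
            # overexposed region covering ~30% of the organism footprint
            ys, xs = np.nonzero(silhouette)
            i = rng.integers(0, ys.size)
            r = math.sqrt(0.3 * silhouette.sum() / math.pi)
            patch = _ellipse_mask(shape, (ys[i], xs[i]), (r, r), 0.0)
            cy3[patch & silhouette] = 65535.0

        planes.append((_quantize(tl), _quantize(cy3), _quantize(fitc)))

    info = {
        "silhouette": silhouette,
        "intended_raw_ratio": raw_ratio,
        "intended_normalized_ratio": normalized,
        "occupancy": occupancy,
        "saturated_patch": bool(saturate),
        "external_aggregate": bool(aggregate),
    }
    return planes, info


# ---------------------------------------------------------------------------
# whole plates


def make_layout(
    truth: SimulationTruth,
    n_individuals: int = 1,
    n_experiments: int = 1,
    n_dead_controls: int = 0,
    timepoint_h: float | None = None,
) -> PlateLayout:
    """Imaging-plate layout: one well per individual per concentration.

    Adds one medium-control and one solvent-control well group per
    experiment (dose 0) and optionally dead-control wells.
    """
    tp = truth.timepoint_h if timepoint_h is None else timepoint_h
    entries = []
    for i_exp in range(1, n_experiments + 1):
        exp = f"E{i_exp}"
        groups = (
            [("CTRL", "control", 0.0), ("SOLV", "solvent_control", 0.0)]
            + [(f"C{i + 1}", "treatment", c)
               for i, c in enumerate(truth.concentrations)]
            + [(f"DEAD{i + 1}", "dead_control", 0.0)
               for i in range(n_dead_controls)]
        )
        for gname, role, conc in groups:
            for rep in range(1, n_individuals + 1):
                suffix = f"R{rep}" if n_individuals > 1 else ""
                entries.append(PlateEntry(
                    well_id=f"{exp}{gname}{suffix}", compound=truth.compound,
                    concentration=conc, unit=truth.unit, role=role,
                    experiment_id=exp, timepoint_h=tp, n_individuals=1,
                ))
    return PlateLayout(entries=tuple(entries))


def generate_plate(
    layout: PlateLayout,
    truth: SimulationTruth,
    phantom: PhantomParams,
    out_dir,
    seed: int,
    force: bool = False,
):
    """Write one TIFF stack per layout entry plus a JSON truth manifest.

    Files follow ``<well>_z<k>_<channel>.tif`` (z 1-based).  Also writes
    ``layout.csv``, ``immobilization.csv`` (binomial draws from the LL2
    truth) and ``truth.json``.  Refuses a non-empty directory unless
    ``force`` is set.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(
            f"{out_dir} is not empty; pass force=True to overwrite"
        )
    out_dir.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(seed)
    manifest = {
        "seed": seed,
        "truth": {
            "ll4": list(truth.ll4), "ll2": list(truth.ll2),
            "concentrations": list(truth.concentrations),
            "noise_sd": truth.noise_sd, "compound": truth.compound,
            "unit": truth.unit, "timepoint_h": truth.timepoint_h,
        },
        "phantom": {
            "control_raw_ratio": phantom.control_raw_ratio,
            "z_levels": phantom.z_levels,
            "image_size_px": list(phantom.image_size_px),
        },
        "wells": {},
    }
    children = ss.spawn(len(layout.entries))
    for entry, child in zip(layout.entries, children):
        rng = np.random.default_rng(child)
        planes, info = generate_well_stack(
            entry.concentration, truth, phantom, rng, role=entry.role
        )
        for iz, (tl, cy3, fitc) in enumerate(planes, start=1):
            for ch, img in (("TL", tl), ("CY3", cy3), ("FITC", fitc)):
                tifffile.imwrite(
                    out_dir / f"{entry.well_id}_z{iz}_{ch}.tif", img
                )
        manifest["wells"][entry.well_id] = {
            "concentration": entry.concentration,
            "role": entry.role,
            "experiment_id": entry.experiment_id,
            "intended_raw_ratio": info["intended_raw_ratio"],
            "intended_normalized_ratio": info["intended_normalized_ratio"],
            "occupancy": info["occupancy"],
            "saturated_patch": info["saturated_patch"],
            "external_aggregate": info["external_aggregate"],
        }

    write_plate_layout(layout, out_dir / "layout.csv")
    imm_truth = SimulationTruth(
        ll4=truth.ll4, ll2=truth.ll2, concentrations=truth.concentrations,
        n_individuals_per_conc=truth.n_individuals_per_conc,
        n_experiments=truth.n_experiments, noise_sd=truth.noise_sd,
        seed=int(ss.spawn(1)[0].generate_state(1, np.uint32)[0] >> 1),
        compound=truth.compound, unit=truth.unit,
        timepoint_h=truth.timepoint_h,
    )
    _, records = simulate_response_tables(imm_truth)
    write_immobilization(records, out_dir / "immobilization.csv")
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
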