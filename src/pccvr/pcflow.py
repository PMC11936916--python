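"""Quantify vessel and whole-brain blood flow from cine velocity data.

Implements the standard phase-contrast workflow: background phase-error
correction against static tissue, per-bin mean velocity x cross-sectional
area per vessel ROI, cycle-mean flow, four-vessel summation to total CBF,
and normalization by brain mass (tissue density 1.06 g/mL) to nCBF in
mL/100 g/min.

Units are fixed throughout: velocity cm/s, area cm^2, flow mL/min
(1 cm^3 = 1 mL, conversion factor 60 s/min).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .synthgen import (BRAIN_TISSUE_DENSITY_G_PER_ML, VESSELS, VelocityCine)

SECONDS_PER_MINUTE = 60.0


@dataclass(frozen=True)
class VesselFlowMeasure:
    """Per-cardiac-bin and cycle-mean flow for one vessel ROI."""

    vessel: str
    mean_velocity_cm_s: np.ndarray   # per bin
    area_cm2: np.ndarray             # per bin
    flow_ml_min: np.ndarray          # per bin
    cycle_mean_flow_ml_min: float

    def __post_init__(self):
        if np.any(np.asarray(self.area_cm2) <= 0):
            raise DataError(f"vessel {self.vessel}: ROI area must be positive")


@dataclass(frozen=True)
class BrainMass:
    """Brain volume and mass, with the fixed tissue-density constant."""

    gm_volume_ml: float
    wm_volume_ml: float
    density_g_per_ml: float = BRAIN_TISSUE_DENSITY_G_PER_ML

    @property
    def total_volume_ml(self) -> float:
        return self.gm_volume_ml + self.wm_volume_ml

    @property
    def mass_g(self) -> float:
        return self.total_volume_ml * self.density_g_per_ml


def correct_background_phase(cine: VelocityCine,
                             mode: str = "constant") -> VelocityCine:
    """Remove background phase errors using the static-tissue mask.

    ``constant`` (default) subtracts, per cardiac bin, the mean velocity over
    static tissue from every voxel; ``planar`` fits and subtracts a first-
    order plane (a + b*x + c*y) to the static voxels of each bin.  Either way
    the corrected static-mask mean is zero (to 1e-9) and the operation is
    idempotent.
    """
    static = cine.static_mask
    if not np.any(static):
        raise DataError("static-tissue mask is empty; cannot correct phase")
    velocity = cine.velocity.copy()
    if mode == "constant":
        offsets = velocity[static, :].mean(axis=0)
        velocity -= offsets[np.newaxis, np.newaxis, :]
    elif mode == "planar":
        nx, ny, _ = velocity.shape
        xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        design = np.column_stack(
            [np.ones(static.sum()), xx[static], yy[static]])
        full = np.column_stack([np.ones(nx * ny), xx.ravel(), yy.ravel()])
        for b in range(velocity.shape[2]):
            coef, *_ = np.linalg.lstsq(design, velocity[static, b], rcond=None)
            velocity[:, :, b] -= (full @ coef).reshape(nx, ny)
    else:
        raise DataError(f"unknown background correction mode {mode!r}")
    return replace_velocity(cine, velocity)


def replace_velocity(cine: VelocityCine, velocity: np.ndarray) -> VelocityCine:
    return VelocityCine(velocity=velocity, pixel_area_cm2=cine.pixel_area_cm2,
                        vessel_masks=cine.vessel_masks,
                        static_mask=cine.static_mask)


def vessel_flow(cine: VelocityCine, vessel: str) -> VesselFlowMeasure:
    """Mean-velocity x area flow for one vessel, per bin and cycle-averaged.

    Area per bin is the ROI pixel count times the pixel area; the cycle mean
    is the unweighted mean over the (equal-duration) cardiac bins.
    """
    if vessel not in cine.vessel_masks:
        raise DataError(f"no ROI mask for vessel {vessel!r}")
    mask = cine.vessel_masks[vessel]
    if not np.any(mask):
        raise DataError(f"ROI mask for vessel {vessel!r} is empty")
    n_bins = cine.n_bins
    area = float(mask.sum()) * cine.pixel_area_cm2
    mean_v = cine.velocity[mask, :].mean(axis=0)           # cm/s per bin
    flow = mean_v * area * SECONDS_PER_MINUTE              # mL/min per bin
    return VesselFlowMeasure(
        vessel=vessel,
        mean_velocity_cm_s=mean_v,
        area_cm2=np.full(n_bins, area),
        flow_ml_min=flow,
        cycle_mean_flow_ml_min=float(flow.mean()))


def total_cbf(measures) -> float:
    """Sum the cycle-mean flows of exactly the four neck vessels (mL/min)."""
    seen = {}
    for m in measures:
        if m.vessel in seen:
            raise DataError(f"duplicate vessel {m.vessel!r}")
        seen[m.vessel] = m.cycle_mean_flow_ml_min
    if set(seen) != set(VESSELS):
        missing = set(VESSELS) - set(seen)
        extra = set(seen) - set(VESSELS)
        raise DataError(
            f"total CBF needs exactly {VESSELS}; missing {sorted(missing)}, "
            f"unexpected {sorted(extra)}")
    return float(sum(seen[v] for v in VESSELS))


def brain_mass(gm_volume_ml: float, wm_volume_ml: float) -> BrainMass:
    """Brain mass from tissue volumes at density 1.06 g/mL."""
    if gm_volume_ml < 0 or wm_volume_ml < 0:
        raise DataError("tissue volumes must be >= 0")
    return BrainMass(gm_volume_ml=float(gm_volume_ml),
                     wm_volume_ml=float(wm_volume_ml))


def normalize_cbf(total_cbf_ml_min: float, mass_g: float) -> float:
    """nCBF = total CBF / brain mass x 100, in mL/100 g/min."""
    if mass_g <= 0:
        raise DataError("brain mass must be positive")
    return total_cbf_ml_min / mass_g * 100.0


def quantify_cine(cine: VelocityCine, correct_background: bool = True,
                  mode: str = "constant") -> dict:
    """Per-vessel cycle-mean flows (mL/min) for one cine."""
    if correct_background:
        cine = correct_background_phase(cine, mode=mode)
    return {v: vessel_flow(cine, v).cycle_mean_flow_ml_min
            for v in cine.vessel_masks}
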