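"""Counts-to-activity quantification chain.

Mirrors the image-based workflow: a calibration factor from a uniform
cylinder scan converts counts to Bq, voxels outside the source-sphere VOI
are zeroed, a volume-level recovery coefficient corrects partial-volume
spill-out, the activity map is resampled to the dose grid, and the CT-like
volume is mapped to densities and materials.

The recovery coefficient is applied as a uniform in-VOI rescale — a
volume-averaged correction cannot be applied voxel by voxel — and the VOI
is the true analytic sphere boundary rasterized on the working grid (a
deliberate simplification that isolates quantification from segmentation
error).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .grids import GridSpec, MaterialGrid, Volume, resample_trilinear
from .materials import ACRYLIC, AIR, WATER
from .nuclide import AdministrationRecord, NuclideData

__all__ = [
    "CalibrationFactor",
    "RecoveryCoefficient",
    "estimate_calibration_factor",
    "counts_to_activity",
    "mask_background",
    "apply_recovery_coefficient",
    "rescale_voi",
    "percent_vs_administered",
    "resample_to_grid",
    "hu_to_density",
    "density_to_material",
]


@dataclass(frozen=True)
class CalibrationFactor:
    """Bq per reconstructed count, with provenance."""

    value_bq_per_count: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.value_bq_per_count <= 0:
            raise ValueError("calibration factor must be > 0")


@dataclass(frozen=True)
class RecoveryCoefficient:
    """Apparent/true concentration ratio for an object of given volume."""

    value: float
    object_volume_ml: float

    def __post_init__(self) -> None:
        if not 0 < self.value <= 1:
            raise ValueError(f"recovery coefficient must be in (0, 1], got {self.value}")


def estimate_calibration_factor(counts: Volume, truth: Volume) -> CalibrationFactor:
    """CF = total true activity / total counts over the calibration phantom."""
    if counts.unit != "counts":
        raise ValueError("counts volume must be tagged 'counts'")
    if truth.unit != "Bq":
        raise ValueError("truth volume must be tagged 'Bq'")
    total_counts = counts.total()
    total_truth = truth.total()
    if total_truth <= 0:
        raise ValueError("calibration truth has no activity")
    if total_counts <= 0:
        raise ValueError("calibration scan recorded zero counts")
    return CalibrationFactor(total_truth / total_counts, "uniform cylinder scan")


def counts_to_activity(counts: Volume, cf: CalibrationFactor) -> Volume:
    """Element-wise counts -> Bq; flips the unit tag."""
    if counts.unit != "counts":
        raise ValueError(f"expected unit 'counts', got {counts.unit!r}")
    return counts.with_values(counts.values * cf.value_bq_per_count, "Bq")


def mask_background(activity: Volume, voi_mask: np.ndarray) -> tuple[Volume, float]:
    """Zero all voxels outside the VOI; returns (masked, removed fraction)."""
    voi_mask = np.asarray(voi_mask, dtype=bool)
    if voi_mask.shape != activity.grid.shape:
        raise ValueError("VOI mask shape does not match the activity grid")
    if not voi_mask.any():
        raise ValueError("VOI is empty")
    total = activity.total()
    masked = np.where(voi_mask, activity.values, 0.0)
    removed = 0.0 if total == 0 else 1.0 - float(masked.sum()) / total
    out = activity.with_values(masked)
    out.meta["background_removed_fraction"] = removed
    return out, removed


def apply_recovery_coefficient(mean_conc_in_voi: float, rc: RecoveryCoefficient) -> float:
    """Partial-volume-corrected mean concentration: mean / RC."""
    if rc.value <= 0:
        raise ValueError("recovery coefficient must be > 0")
    return mean_conc_in_voi / rc.value


def rescale_voi(activity: Volume, voi_mask: np.ndarray, rc: RecoveryCoefficient) -> Volume:
    """Uniformly rescale in-VOI voxels by 1/RC so the VOI mean equals the
    partial-volume-corrected value."""
    voi_mask = np.asarray(voi_mask, dtype=bool)
    out = np.where(voi_mask, activity.values / rc.value, activity.values)
    vol = activity.with_values(out)
    vol.meta["recovery_coefficient"] = rc.value
    return vol


def percent_vs_administered(
    measured_conc_bq_ml: float,
    admin: AdministrationRecord,
    nuclide: NuclideData,
    sphere_volume_ml: float,
) -> float:
    """Percent difference of a measured concentration against the
    decay-corrected administered concentration at scan time:
    100 * (measured - ref) / ref with ref = (A_admin/V) e^(-lambda t_scan)."""
    lam = nuclide.decay_constant_per_day
    ref = admin.a_admin_bq / sphere_volume_ml * math.exp(-lam * admin.t_scan_days)
    return 100.0 * (measured_conc_bq_ml - ref) / ref


def resample_to_grid(
    activity: Volume,
    target: GridSpec,
    voi_masks: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[Volume, float | None]:
    """Trilinear resampling of activity to another grid.

    Concentration (intensive) is interpolated, then converted back to
    per-voxel Bq on the target voxel volume.  If VOI masks on the source
    and target grids are supplied, the relative change of the VOI mean
    concentration is reported (a resampling diagnostic).
    """
    if activity.unit != "Bq":
        raise ValueError("activity must be tagged 'Bq'")
    if not activity.grid.overlaps(target):
        raise ValueError("source and target grids are disjoint")
    conc = activity.to_concentration()
    conc_rs = resample_trilinear(conc, target)
    out = Volume(target, conc_rs.values * target.voxel_volume_ml, "Bq", dict(activity.meta))
    rel_change = None
    if voi_masks is not None:
        src_mask, tgt_mask = voi_masks
        m0 = float(conc.values[np.asarray(src_mask, dtype=bool)].mean())
        m1 = float(conc_rs.values[np.asarray(tgt_mask, dtype=bool)].mean())
        rel_change = (m1 - m0) / m0 if m0 != 0 else None
        out.meta["resample_voi_mean_rel_change"] = rel_change
    return out, rel_change


# density thresholds for material classification, g/cm^3
_AIR_MAX = 0.05
_WATER_MAX = 1.10
_DENSITY_MIN, _DENSITY_MAX = 0.0, 3.0


def hu_to_density(ct: Volume) -> Volume:
    """Piecewise-linear CT-number -> density (inverse of the acquisition
    map: -1000 -> 0.001 g/cm^3, 0 -> 1.0, slope 0.001 g/cm^3 per HU above
    water).  Values outside the physical range are clamped with a warning."""
    if ct.unit != "HU":
        raise ValueError(f"expected unit 'HU', got {ct.unit!r}")
    hu = np.asarray(ct.values, dtype=np.float64)
    below = 0.001 + (hu + 1000.0) * (0.999 / 1000.0)
    above = 1.0 + hu / 1000.0
    rho = np.where(hu <= 0.0, below, above)
    if np.any(rho < _DENSITY_MIN) or np.any(rho > _DENSITY_MAX):
        warnings.warn("CT-derived densities clamped to physical range", stacklevel=2)
        rho = np.clip(rho, 0.001, _DENSITY_MAX)
    return Volume(ct.grid, rho, "g/cm3")


def density_to_material(density: Volume) -> MaterialGrid:
    """Threshold densities into air / water-like / acrylic material codes."""
    if density.unit != "g/cm3":
        raise ValueError(f"expected unit 'g/cm3', got {density.unit!r}")
    rho = np.asarray(density.values)
    codes = np.full(density.grid.shape, WATER.code, dtype=np.int8)
    codes[rho < _AIR_MAX] = AIR.code
    codes[rho >= _WATER_MAX] = ACRYLIC.code
    densities = {AIR.code: AIR.density, WATER.code: WATER.density, ACRYLIC.code: ACRYLIC.density}
    return MaterialGrid(density.grid, codes, densities)
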