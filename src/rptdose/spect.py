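"""Synthetic SPECT/CT image formation.

Projection, reconstruction, collimator-detector-response modeling and
scatter correction are replaced by an image-domain surrogate: resolution
loss as an isotropic Gaussian PSF, a global sensitivity x duration count
scale, and post-blur Poisson noise.  This reproduces the phenomena the
quantification chain corrects for (partial volume, calibration, noise) at
desk scale; Gibbs ringing from resolution modeling is not reproduced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import GridSpec, MaterialGrid, Volume, resample_trilinear
from .materials import AIR
from .phantom import sphere_radius_mm

__all__ = [
    "ScannerModel",
    "simulate_spect",
    "simulate_ct",
    "calibration_scan",
    "measure_recovery_coefficient",
    "density_to_hu",
]

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def default_spect_grid() -> GridSpec:
    return GridSpec.centered((128, 128, 128), (4.42, 4.42, 4.42))


def default_ct_grid() -> GridSpec:
    return GridSpec.centered((247, 253, 52), (0.977, 0.977, 5.0))


@dataclass(frozen=True)
class ScannerModel:
    """Image-formation surrogate parameters.

    ``sensitivity_cps_per_bq`` is the count rate per Bq per voxel of the
    reconstructed image; expected counts = sensitivity x duration x
    activity.  ``psf_fwhm_mm`` is the isotropic Gaussian stand-in for the
    collimator-detector response at 364 keV.
    """

    psf_fwhm_mm: float = 12.0
    sensitivity_cps_per_bq: float = 1.0e-5
    scan_duration_s: float = 3600.0  # 120 projections x 30 s
    spect_grid: GridSpec = field(default_factory=default_spect_grid)
    ct_grid: GridSpec = field(default_factory=default_ct_grid)
    noise: str = "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be >= 0")
        if self.sensitivity_cps_per_bq <= 0 or self.scan_duration_s <= 0:
            raise ValueError("sensitivity and scan duration must be > 0")
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise must be 'poisson' or 'none'")


def _blur(values: np.ndarray, grid: GridSpec, fwhm_mm: float) -> np.ndarray:
    if fwhm_mm == 0:
        return np.asarray(values, dtype=np.float64)
    sigmas = [fwhm_mm / _FWHM_TO_SIGMA / s for s in grid.spacing]
    return ndimage.gaussian_filter(
        np.asarray(values, dtype=np.float64), sigmas, mode="constant", cval=0.0
    )


def simulate_spect(truth: Volume, scanner: ScannerModel) -> Volume:
    """Emulated SPECT acquisition: blurred, scaled, Poisson-sampled counts."""
    if truth.unit != "Bq":
        raise ValueError(f"truth must be tagged Bq, got {truth.unit}")
    if truth.grid == scanner.spect_grid:
        act = np.asarray(truth.values, dtype=np.float64)
    else:
        if not truth.grid.overlaps(scanner.spect_grid):
            raise ValueError("truth grid does not overlap the SPECT grid")
        conc = truth.to_concentration()
        act = (
            resample_trilinear(conc, scanner.spect_grid).values
            * scanner.spect_grid.voxel_volume_ml
        )
    expected = (
        _blur(act, scanner.spect_grid, scanner.psf_fwhm_mm)
        * scanner.sensitivity_cps_per_bq
        * scanner.scan_duration_s
    )
    if scanner.noise == "poisson":
        rng = np.random.default_rng(scanner.seed)
        counts = rng.poisson(expected).astype(np.float64)
    else:
        counts = expected
    return Volume(scanner.spect_grid, counts, "counts", {"psf_fwhm_mm": scanner.psf_fwhm_mm})


def density_to_hu(density: np.ndarray) -> np.ndarray:
    """Piecewise-linear density -> CT-number map (anchors 0.001 -> -1000,
    1.0 -> 0, slope 1000 HU per g/cm^3 above water)."""
    rho = np.asarray(density, dtype=np.float64)
    below = -1000.0 + (rho - 0.001) * (1000.0 / 0.999)
    above = 1000.0 * (rho - 1.0)
    return np.where(rho <= 1.0, below, above)


def simulate_ct(materials: MaterialGrid, scanner: ScannerModel) -> Volume:
    """CT-number-like volume from the material densities, on the CT grid."""
    dens = materials.density_volume()
    hu = Volume(dens.grid, density_to_hu(dens.values), "HU")
    if hu.grid == scanner.ct_grid:
        return hu
    # resample in density space so air/water mixing stays physical
    dens_rs = resample_trilinear(dens, scanner.ct_grid, cval=AIR.density)
    return Volume(scanner.ct_grid, density_to_hu(dens_rs.values), "HU")


def _rasterize_fraction(
    indicator, grid: GridSpec, subsamples: int = 2, bbox=None
) -> np.ndarray:
    """Fraction of each voxel inside an analytic region, by point sampling.

    ``bbox = (lo_mm, hi_mm)`` restricts the sampled index window (the
    region is assumed empty outside it)."""
    offs = (np.arange(subsamples) + 0.5) / subsamples - 0.5
    frac = np.zeros(grid.shape, dtype=np.float64)
    if bbox is None:
        lo = np.zeros(3, dtype=int)
        hi = np.asarray(grid.shape)
    else:
        lo = np.clip(np.floor(grid.world_to_index(bbox[0])).astype(int), 0, grid.shape)
        hi = np.clip(np.ceil(grid.world_to_index(bbox[1])).astype(int) + 1, 0, grid.shape)
    xs = grid.voxel_centers(0)[lo[0]: hi[0]]
    ys = grid.voxel_centers(1)[lo[1]: hi[1]]
    zs = grid.voxel_centers(2)[lo[2]: hi[2]]
    sub = np.zeros((len(xs), len(ys), len(zs)))
    for ox in offs:
        for oy in offs:
            for oz in offs:
                px = xs + ox * grid.spacing[0]
                py = ys + oy * grid.spacing[1]
                pz = zs + oz * grid.spacing[2]
                sub += indicator(
                    px[:, None, None], py[None, :, None], pz[None, None, :]
                )
    frac[lo[0]: hi[0], lo[1]: hi[1], lo[2]: hi[2]] = sub
    return frac / subsamples**3


def calibration_scan(
    cylinder_volume_l: float,
    uniform_conc_bq_ml: float,
    scanner: ScannerModel,
    cylinder_radius_mm: float = 108.0,
) -> tuple[Volume, Volume]:
    """Simulated scan of a uniformly filled calibration cylinder.

    Returns ``(counts, truth)`` where ``truth`` is the ground-truth
    per-voxel activity (Bq) on the SPECT grid, for calibration-factor
    estimation downstream.
    """
    if uniform_conc_bq_ml <= 0:
        raise ValueError("uniform concentration must be > 0")
    height = cylinder_volume_l * 1e6 / (math.pi * cylinder_radius_mm**2)

    def inside(x, y, z):
        return (x**2 + y**2 <= cylinder_radius_mm**2) & (np.abs(z) <= 0.5 * height)

    frac = _rasterize_fraction(inside, scanner.spect_grid, subsamples=2)
    truth = Volume(
        scanner.spect_grid,
        frac * uniform_conc_bq_ml * scanner.spect_grid.voxel_volume_ml,
        "Bq",
    )
    counts = simulate_spect(truth, scanner)
    return counts, truth


def measure_recovery_coefficient(
    sphere_volume_ml: float,
    scanner: ScannerModel,
    background_conc_bq_ml: float = 0.0,
    sphere_conc_bq_ml: float = 1.0e6,
) -> float:
    """Recovery coefficient of a sphere under this scanner's resolution model.

    A sphere of known concentration is imaged noise-free (the RC
    characterizes the deterministic resolution loss) and quantified with
    the true analytic sphere boundary as the VOI, exactly as the pipeline
    quantifies the source.  RC is the ratio of the apparent (blurred) VOI
    mean to the VOI mean of the same digitized sphere without blur, so it
    isolates the point-spread spill-out: RC = 1 exactly at zero PSF and
    decreases monotonically with PSF width.
    """
    if sphere_volume_ml <= 0:
        raise ValueError("sphere volume must be > 0")
    r = sphere_radius_mm(sphere_volume_ml)
    grid = scanner.spect_grid

    def inside(x, y, z):
        return x**2 + y**2 + z**2 <= r**2

    frac = _rasterize_fraction(
        inside, grid, subsamples=4, bbox=(-(r + 1) * np.ones(3), (r + 1) * np.ones(3))
    )
    conc = background_conc_bq_ml + frac * (sphere_conc_bq_ml - background_conc_bq_ml)
    blurred = _blur(conc, grid, scanner.psf_fwhm_mm)
    xs = grid.voxel_centers(0)[:, None, None]
    ys = grid.voxel_centers(1)[None, :, None]
    zs = grid.voxel_centers(2)[None, None, :]
    voi = (xs**2 + ys**2 + zs**2) <= r**2
    apparent = float(blurred[voi].mean())
    unblurred = float(conc[voi].mean())
    return (apparent - background_conc_bq_ml) / (unblurred - background_conc_bq_ml)
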