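"""Stylized phantom: water-filled cylinder, hollow source sphere, TLD probes.

The geometry mirrors a 6.4 L Jaszczak-style cylinder holding a 16 ml source
sphere and six acrylic probe rods.  Each probe is modeled as a single
vertical acrylic cylinder (post and cap merged) whose scoring point sits at
a configured position; o-rings, studs and threads are sub-voxel and
ignored.  All coordinates are world mm; the cylinder axis is z.

``build_phantom`` returns an analytic constructive description whose region
predicates take broadcastable per-axis coordinate arrays; ``voxelize``
rasterizes it onto any :class:`~rptdose.grids.GridSpec` by sub-voxel point
sampling with majority-vote materials and exactly conservative activity
apportioning.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .grids import GridSpec, MaterialGrid, Volume
from .materials import MATERIALS_BY_NAME

__all__ = [
    "ConfigurationError",
    "PhantomConfig",
    "PhantomGeometry",
    "build_phantom",
    "voxelize",
    "voxelize_activity",
    "sphere_voi_mask",
    "sphere_radius_mm",
]

#: default scorer positions (mm, relative to the sphere center at the origin),
#: staggered over ~3-9 cm so the photon dose spans roughly a 10x range
DEFAULT_PROBE_POSITIONS = (
    (28.0, 0.0, 10.0),
    (0.0, 45.0, -15.0),
    (-60.0, 0.0, 20.0),
    (0.0, -75.0, -20.0),
    (62.0, 62.0, 0.0),
    (-24.0, 18.0, -12.0),
)


class ConfigurationError(ValueError):
    """Raised for geometrically inconsistent phantom configurations."""


def sphere_radius_mm(volume_ml: float) -> float:
    """Radius of a sphere of the given volume: r = (3V / 4 pi)^(1/3)."""
    if volume_ml <= 0:
        raise ValueError("sphere volume must be > 0")
    return (3.0 * volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class PhantomConfig:
    cylinder_volume_l: float = 6.4
    cylinder_radius_mm: float = 108.0  # standard flangeless Jaszczak
    sphere_volume_ml: float = 16.0
    sphere_center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    probe_positions_mm: tuple[tuple[float, float, float], ...] = DEFAULT_PROBE_POSITIONS
    probe_rod_diameter_mm: float = 12.7  # 1/2 inch acrylic rod
    probe_post_height_mm: float = 96.5
    probe_cap_height_mm: float = 15.2
    materials: tuple[tuple[str, str], ...] = (
        ("background", "air"),
        ("cylinder", "water"),
        ("sphere", "water"),
        ("probe", "acrylic"),
    )

    @property
    def cylinder_height_mm(self) -> float:
        """Height solved from volume: h = V / (pi r^2)."""
        return self.cylinder_volume_l * 1e6 / (math.pi * self.cylinder_radius_mm**2)

    @property
    def sphere_radius_mm(self) -> float:
        return sphere_radius_mm(self.sphere_volume_ml)

    def material_for(self, region: str) -> int:
        name = dict(self.materials)[region]
        return MATERIALS_BY_NAME[name].code


@dataclass(frozen=True)
class PhantomGeometry:
    """Analytic constructive description produced by :func:`build_phantom`.

    Region predicates take broadcastable coordinate arrays (x, y, z in mm)
    and return boolean arrays of the broadcast shape.
    """

    config: PhantomConfig
    cylinder_radius_mm: float
    cylinder_height_mm: float
    sphere_center: np.ndarray
    sphere_radius_mm: float
    probe_axes_xy: np.ndarray  # (n_probes, 2)
    probe_tops_z: np.ndarray  # (n_probes,)
    rod_radius_mm: float

    def in_sphere(self, x, y, z) -> np.ndarray:
        cx, cy, cz = self.sphere_center
        return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= self.sphere_radius_mm**2

    def in_cylinder(self, x, y, z) -> np.ndarray:
        half_h = 0.5 * self.cylinder_height_mm
        return (x**2 + y**2 <= self.cylinder_radius_mm**2) & (np.abs(z) <= half_h)

    def in_probe(self, x, y, z) -> np.ndarray:
        z_bottom = -0.5 * self.cylinder_height_mm
        hit = np.zeros(np.broadcast_shapes(np.shape(x), np.shape(y), np.shape(z)), bool)
        for (ax, ay), z_top in zip(self.probe_axes_xy, self.probe_tops_z):
            hit |= (
                ((x - ax) ** 2 + (y - ay) ** 2 <= self.rod_radius_mm**2)
                & (z >= z_bottom)
                & (z <= z_top)
            )
        return hit

    def classify(self, x, y, z) -> tuple[np.ndarray, np.ndarray]:
        """(material codes, activity indicator); probe > sphere > cylinder."""
        cfg = self.config
        shape = np.broadcast_shapes(np.shape(x), np.shape(y), np.shape(z))
        out = np.full(shape, cfg.material_for("background"), dtype=np.int8)
        out[self.in_cylinder(x, y, z)] = cfg.material_for("cylinder")
        sph = self.in_sphere(x, y, z)
        out[sph] = cfg.material_for("sphere")
        prb = self.in_probe(x, y, z)
        out[prb] = cfg.material_for("probe")
        return out, sph & ~prb

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        r, h = self.cylinder_radius_mm, self.cylinder_height_mm
        return np.array([-r, -r, -0.5 * h]), np.array([r, r, 0.5 * h])

    def density_table(self) -> dict[int, float]:
        return {
            MATERIALS_BY_NAME[n].code: MATERIALS_BY_NAME[n].density
            for _, n in self.config.materials
        }


def build_phantom(config: PhantomConfig) -> PhantomGeometry:
    """Validate the configuration and return the analytic geometry."""
    r_cyl = config.cylinder_radius_mm
    h_cyl = config.cylinder_height_mm
    r_sph = config.sphere_radius_mm
    c = np.asarray(config.sphere_center_mm, dtype=float)

    if math.hypot(c[0], c[1]) + r_sph > r_cyl or abs(c[2]) + r_sph > 0.5 * h_cyl:
        raise ConfigurationError("source sphere is not fully inside the cylinder")

    rod_r = 0.5 * config.probe_rod_diameter_mm
    axes, tops = [], []
    for i, (px, py, pz) in enumerate(config.probe_positions_mm):
        z_top = pz + 0.5 * config.probe_cap_height_mm
        axes.append((px, py))
        tops.append(z_top)
        # probe rod spans z in [cylinder bottom, z_top] at fixed (px, py)
        axis_dist = math.hypot(px - c[0], py - c[1])
        z_overlap = min(z_top, c[2] + r_sph) >= max(-0.5 * h_cyl, c[2] - r_sph)
        if z_overlap and axis_dist < r_sph + rod_r:
            raise ConfigurationError(
                f"probe {i} (xy distance {axis_dist:.1f} mm) intersects the source sphere"
            )
        if math.hypot(px, py) + rod_r > r_cyl or z_top > 0.5 * h_cyl:
            raise ConfigurationError(f"probe {i} extends outside the cylinder")

    return PhantomGeometry(
        config=config,
        cylinder_radius_mm=r_cyl,
        cylinder_height_mm=h_cyl,
        sphere_center=c,
        sphere_radius_mm=r_sph,
        probe_axes_xy=np.asarray(axes, dtype=float),
        probe_tops_z=np.asarray(tops, dtype=float),
        rod_radius_mm=rod_r,
    )


def _offsets(subsamples: int) -> np.ndarray:
    """Per-axis fractional offsets (voxel units) of the sampling lattice."""
    return (np.arange(subsamples) + 0.5) / subsamples - 0.5


def _check_coverage(geometry: PhantomGeometry, grid: GridSpec) -> None:
    lo_g, hi_g = grid.bounds()
    lo_p, hi_p = geometry.bounding_box()
    if np.any(lo_g > lo_p) or np.any(hi_g < hi_p):
        warnings.warn("grid does not cover the phantom bounding box", stacklevel=3)


def voxelize(
    geometry: PhantomGeometry,
    grid: GridSpec,
    subsamples: int = 2,
    total_activity_bq: float = 0.0,
) -> tuple[MaterialGrid, Volume]:
    """Rasterize the analytic phantom onto a voxel grid.

    Each voxel's material is the majority vote over ``subsamples**3`` sample
    points; activity is apportioned by the per-voxel fraction of sample
    points inside the source region, normalized so the voxelized total
    equals ``total_activity_bq`` exactly.
    """
    if subsamples < 1:
        raise ValueError("subsamples must be >= 1")
    _check_coverage(geometry, grid)
    offs = _offsets(subsamples)
    codes = sorted({MATERIALS_BY_NAME[n].code for _, n in geometry.config.materials})
    counts = np.zeros((len(codes),) + grid.shape, dtype=np.uint16)
    frac = np.zeros(grid.shape, dtype=np.float64)
    xs, ys, zs = (grid.voxel_centers(a) for a in range(3))
    for ox, oy, oz in itertools.product(offs, offs, offs):
        x = (xs + ox * grid.spacing[0])[:, None, None]
        y = (ys + oy * grid.spacing[1])[None, :, None]
        z = (zs + oz * grid.spacing[2])[None, None, :]
        mats, act = geometry.classify(x, y, z)
        for ci, c in enumerate(codes):
            counts[ci] += mats == c
        frac += act

    mat_out = np.asarray(codes, dtype=np.int8)[counts.argmax(axis=0)]
    frac /= subsamples**3
    total = frac.sum()
    if total_activity_bq > 0 and total == 0:
        raise ConfigurationError("no sample point fell inside the source region")
    activity = frac * (total_activity_bq / total) if total_activity_bq > 0 else frac
    return (
        MaterialGrid(grid, mat_out, geometry.density_table()),
        Volume(grid, activity, "Bq"),
    )


def voxelize_activity(
    geometry: PhantomGeometry,
    grid: GridSpec,
    subsamples: int = 4,
    total_activity_bq: float = 0.0,
) -> Volume:
    """Rasterize only the source region (fast path restricted to the sphere's
    bounding box); activity apportioning is exactly conservative."""
    if subsamples < 1:
        raise ValueError("subsamples must be >= 1")
    _check_coverage(geometry, grid)
    c, r = geometry.sphere_center, geometry.sphere_radius_mm
    lo = np.floor(grid.world_to_index(c - r - 1.0)).astype(int)
    hi = np.ceil(grid.world_to_index(c + r + 1.0)).astype(int) + 1
    lo = np.clip(lo, 0, np.asarray(grid.shape))
    hi = np.clip(hi, 0, np.asarray(grid.shape))
    frac = np.zeros(grid.shape, dtype=np.float64)
    offs = _offsets(subsamples)
    xs = grid.voxel_centers(0)[lo[0]: hi[0]]
    ys = grid.voxel_centers(1)[lo[1]: hi[1]]
    zs = grid.voxel_centers(2)[lo[2]: hi[2]]
    sub = np.zeros((len(xs), len(ys), len(zs)))
    for ox, oy, oz in itertools.product(offs, offs, offs):
        x = (xs + ox * grid.spacing[0])[:, None, None]
        y = (ys + oy * grid.spacing[1])[None, :, None]
        z = (zs + oz * grid.spacing[2])[None, None, :]
        sub += geometry.in_sphere(x, y, z) & ~geometry.in_probe(x, y, z)
    frac[lo[0]: hi[0], lo[1]: hi[1], lo[2]: hi[2]] = sub / subsamples**3
    total = frac.sum()
    if total_activity_bq > 0 and total == 0:
        raise ConfigurationError("no sample point fell inside the source region")
    activity = frac * (total_activity_bq / total) if total_activity_bq > 0 else frac
    return Volume(grid, activity, "Bq")


def sphere_voi_mask(geometry: PhantomGeometry, grid: GridSpec) -> np.ndarray:
    """Voxels whose centers lie inside the true (analytic) source sphere."""
    xs = grid.voxel_centers(0)[:, None, None]
    ys = grid.voxel_centers(1)[None, :, None]
    zs = grid.voxel_centers(2)[None, None, :]
    return geometry.in_sphere(xs, ys, zs)
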