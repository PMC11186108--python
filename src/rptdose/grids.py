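"""Voxel grid geometry and unit-tagged volumes.

World coordinates are right-handed and in millimetres.  A :class:`GridSpec`
addresses voxel *centers*: the world coordinate of voxel index ``(0, 0, 0)``
is ``origin``, and index ``(i, j, k)`` maps to ``origin + index * spacing``.
Two grids with different spacings (e.g. the SPECT grid and the CT/dose grid)
co-register through these world coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["GridSpec", "Volume", "resample_trilinear"]

#: unit tags a Volume may carry
VALID_UNITS = ("Bq", "Bq/ml", "counts", "Gy", "Gy/history", "HU", "g/cm3", "1")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a 3-D voxel grid (shape, mm spacing, mm origin)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"shape must be three integers >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be > 0, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_centers(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel index of world points."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """World-space bounding box of the grid (voxel edges, not centers)."""
        o = np.asarray(self.origin)
        s = np.asarray(self.spacing)
        n = np.asarray(self.shape)
        return o - 0.5 * s, o + (n - 0.5) * s

    def overlaps(self, other: "GridSpec") -> bool:
        lo_a, hi_a = self.bounds()
        lo_b, hi_b = other.bounds()
        return bool(np.all(lo_a < hi_b) and np.all(lo_b < hi_a))

    @classmethod
    def centered(
        cls,
        shape: tuple[int, int, int],
        spacing: tuple[float, float, float],
        center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "GridSpec":
        """Grid whose world-space center is ``center``."""
        origin = tuple(
            c - 0.5 * (n - 1) * s for c, n, s in zip(center, shape, spacing)
        )
        return cls(shape, spacing, origin)


@dataclass
class Volume:
    """A 3-D scalar field on a :class:`GridSpec` with an explicit unit tag.

    Serves as ActivityGrid (``Bq``, ``Bq/ml`` or ``counts``), CT-number
    volume (``HU``), density volume (``g/cm3``) and dose container.
    """

    grid: GridSpec
    values: np.ndarray
    unit: str = "1"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if tuple(self.values.shape) != self.grid.shape:
            raise ValueError(
                f"value array shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit tag {self.unit!r}; expected one of {VALID_UNITS}")

    def total(self) -> float:
        return float(self.values.sum())

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "Volume":
        return Volume(self.grid, values, unit or self.unit, dict(self.meta))

    def to_concentration(self) -> "Volume":
        """Per-voxel Bq -> Bq/ml."""
        if self.unit != "Bq":
            raise ValueError(f"expected unit Bq, got {self.unit}")
        return self.with_values(self.values / self.grid.voxel_volume_ml, "Bq/ml")

    def to_activity(self) -> "Volume":
        """Bq/ml -> per-voxel Bq."""
        if self.unit != "Bq/ml":
            raise ValueError(f"expected unit Bq/ml, got {self.unit}")
        return self.with_values(self.values * self.grid.voxel_volume_ml, "Bq")


@dataclass
class MaterialGrid:
    """Per-voxel material codes with a density table (g/cm^3)."""

    grid: GridSpec
    material_index: np.ndarray
    densities: dict[int, float]

    def __post_init__(self) -> None:
        self.material_index = np.asarray(self.material_index)
        if tuple(self.material_index.shape) != self.grid.shape:
            raise ValueError("material_index shape does not match grid")
        codes = np.unique(self.material_index)
        missing = [int(c) for c in codes if int(c) not in self.densities]
        if missing:
            raise ValueError(f"material codes without density entries: {missing}")
        if any(rho <= 0 for rho in self.densities.values()):
            raise ValueError("all densities must be > 0")

    def density_volume(self) -> Volume:
        out = np.zeros(self.grid.shape, dtype=np.float64)
        for code, rho in self.densities.items():
            out[self.material_index == code] = rho
        return Volume(self.grid, out, "g/cm3")


def resample_trilinear(vol: Volume, target: GridSpec, *, cval: float = 0.0) -> Volume:
    """Trilinear resampling of a volume onto ``target`` via world coordinates.

    Interpolates the stored values as an intensive field; callers resampling
    per-voxel activity should convert to concentration first (see
    :func:`rptdose.quantify.resample_to_grid`).
    """
    if not vol.grid.overlaps(target):
        raise ValueError("source and target grids do not overlap")
    # fractional source indices of every target voxel center
    axes = [
        (target.voxel_centers(a) - vol.grid.origin[a]) / vol.grid.spacing[a]
        for a in range(3)
    ]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(
        np.asarray(vol.values, dtype=np.float64),
        [ii, jj, kk],
        order=1,
        mode="constant",
        cval=cval,
    )
    return Volume(target, out, vol.unit, dict(vol.meta))
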