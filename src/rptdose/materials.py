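"""Material registry for the phantom: codes, densities, elemental composition.

The pipeline only needs low-Z media: air, water, acrylic (PMMA) for the
probe bodies, and polystyrene. Compositions are mass fractions; densities in
g/cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Material", "MATERIALS", "AIR", "WATER", "ACRYLIC", "POLYSTYRENE"]

# element -> (Z, A)
_ELEMENTS = {
    "H": (1, 1.008),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
    "Ar": (18, 39.948),
}


@dataclass(frozen=True)
class Material:
    code: int
    name: str
    density: float  # g/cm^3
    composition: tuple[tuple[str, float], ...]  # (element, mass fraction)

    def electrons_per_gram(self) -> float:
        """N_A * sum_i w_i Z_i / A_i."""
        na = 6.02214076e23
        return na * sum(w * _ELEMENTS[el][0] / _ELEMENTS[el][1] for el, w in self.composition)

    def photoelectric_weight(self) -> float:
        """sum_i w_i Z_i^4.5 / A_i — weight for the parametric tau/rho fit."""
        return sum(
            w * _ELEMENTS[el][0] ** 4.5 / _ELEMENTS[el][1] for el, w in self.composition
        )


AIR = Material(
    0, "air", 0.001205,
    (("N", 0.7552), ("O", 0.2318), ("Ar", 0.0128), ("C", 0.0002)),
)
WATER = Material(1, "water", 1.000, (("H", 0.1119), ("O", 0.8881)))
ACRYLIC = Material(2, "acrylic", 1.190, (("H", 0.0805), ("C", 0.5998), ("O", 0.3196)))
POLYSTYRENE = Material(3, "polystyrene", 1.060, (("H", 0.0774), ("C", 0.9226)))

MATERIALS: dict[int, Material] = {m.code: m for m in (AIR, WATER, ACRYLIC, POLYSTYRENE)}
MATERIALS_BY_NAME: dict[str, Material] = {m.name: m for m in MATERIALS.values()}
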