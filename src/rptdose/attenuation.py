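"""Photon interaction coefficients for the voxel Monte Carlo engine.

Tables are computed from elemental composition over 10-800 keV:

* incoherent scattering from the analytic Klein-Nishina free-electron cross
  section times the electron density (exact for free electrons; binding
  corrections of a few percent below ~100 keV are neglected),
* photoelectric absorption from a parametric ``Z^4.5 / E^3`` fit anchored to
  water at 30 keV,
* the mass energy-transfer coefficient mu_tr/rho, used by the track-length
  kerma estimator, from the photoelectric term (full energy transfer) plus
  the Klein-Nishina mean electron-energy fraction.

Coherent (Rayleigh) scattering, characteristic x rays and bremsstrahlung are
intentionally omitted; total = photoelectric + incoherent.  Tables can be
serialized to / loaded from CSV for inspection or override.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .materials import MATERIALS, Material

__all__ = [
    "CrossSectionTable",
    "klein_nishina_total",
    "klein_nishina_mean_scatter_fraction",
    "build_table",
]

_R_E_CM = 2.8179403262e-13  # classical electron radius, cm
_MEC2_KEV = 510.99895
# tau/rho(water, 30 keV) anchor for the parametric photoelectric fit, cm^2/g
_PE_ANCHOR = 0.147
_PE_ANCHOR_E = 30.0
_PE_WATER_WEIGHT = 643.2  # sum w_i Z_i^4.5 / A_i for water


def klein_nishina_total(energy_kev: np.ndarray) -> np.ndarray:
    """Total Klein-Nishina cross section per electron, cm^2."""
    k = np.asarray(energy_kev, dtype=np.float64) / _MEC2_KEV
    t1 = (1 + k) / k**2 * (2 * (1 + k) / (1 + 2 * k) - np.log1p(2 * k) / k)
    t2 = np.log1p(2 * k) / (2 * k)
    t3 = (1 + 3 * k) / (1 + 2 * k) ** 2
    return 2 * np.pi * _R_E_CM**2 * (t1 + t2 - t3)


def _kn_differential(k: np.ndarray, cos_t: np.ndarray) -> np.ndarray:
    """d(sigma)/d(cos theta) per electron (unnormalized by 2*pi*r_e^2/2)."""
    ratio = 1.0 / (1.0 + k * (1.0 - cos_t))  # E'/E
    return ratio**2 * (ratio + 1.0 / ratio - (1.0 - cos_t**2))


def klein_nishina_mean_scatter_fraction(energy_kev: np.ndarray) -> np.ndarray:
    """Mean scattered-photon energy fraction <E'/E> under Klein-Nishina."""
    e = np.atleast_1d(np.asarray(energy_kev, dtype=np.float64))
    k = e / _MEC2_KEV
    cos_t = np.linspace(-1.0, 1.0, 4001)
    kk = k[:, None]
    w = _kn_differential(kk, cos_t[None, :])
    ratio = 1.0 / (1.0 + kk * (1.0 - cos_t[None, :]))
    num = np.trapezoid(w * ratio, cos_t, axis=1)
    den = np.trapezoid(w, cos_t, axis=1)
    out = num / den
    return out if np.ndim(energy_kev) else float(out[0])


@dataclass
class CrossSectionTable:
    """Log-spaced interaction-coefficient tables per material code.

    All mass coefficients in cm^2/g; linear coefficients derived with the
    stored densities (g/cm^3).  Energies in keV, strictly increasing.
    """

    energies: np.ndarray
    mu_rho_pe: dict[int, np.ndarray]
    mu_rho_incoh: dict[int, np.ndarray]
    mu_tr_rho: dict[int, np.ndarray]
    densities: dict[int, float]

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=np.float64)
        if not np.all(np.diff(self.energies) > 0):
            raise ValueError("energy grid must be strictly increasing")
        for code in self.mu_rho_pe:
            if np.any(self.mu_rho_pe[code] < 0) or np.any(self.mu_rho_incoh[code] <= 0):
                raise ValueError("cross sections must be positive")

    @property
    def codes(self) -> list[int]:
        return sorted(self.mu_rho_pe)

    def _interp(self, table: np.ndarray, energy_kev: np.ndarray) -> np.ndarray:
        e = np.clip(energy_kev, self.energies[0], self.energies[-1])
        return np.exp(
            np.interp(np.log(e), np.log(self.energies), np.log(np.maximum(table, 1e-30)))
        )

    def mu_rho_total(self, code: int, energy_kev: np.ndarray) -> np.ndarray:
        return self._interp(
            self.mu_rho_pe[code] + self.mu_rho_incoh[code], energy_kev
        )

    def mu_linear(self, code: int, energy_kev: np.ndarray) -> np.ndarray:
        """Linear attenuation coefficient, 1/cm."""
        return self.densities[code] * self.mu_rho_total(code, energy_kev)

    def pe_fraction(self, code: int, energy_kev: np.ndarray) -> np.ndarray:
        """Photoelectric share of the total interaction probability."""
        pe = self._interp(self.mu_rho_pe[code], energy_kev)
        tot = self.mu_rho_total(code, energy_kev)
        return pe / tot

    def mu_tr_over_rho(self, code: int, energy_kev: np.ndarray) -> np.ndarray:
        """Mass energy-transfer coefficient, cm^2/g."""
        return self._interp(self.mu_tr_rho[code], energy_kev)

    def majorant_mu(self, energy_kev: np.ndarray, codes=None) -> np.ndarray:
        """Max linear attenuation over materials, for Woodcock tracking."""
        codes = self.codes if codes is None else list(codes)
        mus = np.stack([self.mu_linear(c, energy_kev) for c in codes])
        return mus.max(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for code in self.codes:
            for i, e in enumerate(self.energies):
                rows.append(
                    {
                        "material_code": code,
                        "energy_keV": e,
                        "mu_rho_photoelectric_cm2_g": self.mu_rho_pe[code][i],
                        "mu_rho_incoherent_cm2_g": self.mu_rho_incoh[code][i],
                        "mu_rho_total_cm2_g": self.mu_rho_pe[code][i]
                        + self.mu_rho_incoh[code][i],
                        "mu_tr_rho_cm2_g": self.mu_tr_rho[code][i],
                        "density_g_cm3": self.densities[code],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CrossSectionTable":
        df = pd.read_csv(path)
        energies = np.sort(df["energy_keV"].unique())
        pe, inc, tr, dens = {}, {}, {}, {}
        for code, sub in df.groupby("material_code"):
            sub = sub.sort_values("energy_keV")
            pe[int(code)] = sub["mu_rho_photoelectric_cm2_g"].to_numpy()
            inc[int(code)] = sub["mu_rho_incoherent_cm2_g"].to_numpy()
            tr[int(code)] = sub["mu_tr_rho_cm2_g"].to_numpy()
            dens[int(code)] = float(sub["density_g_cm3"].iloc[0])
        return cls(energies, pe, inc, tr, dens)


def build_table(
    materials: dict[int, Material] | None = None,
    e_min_kev: float = 10.0,
    e_max_kev: float = 800.0,
    n_points: int = 120,
) -> CrossSectionTable:
    """Compute interaction tables for the given materials."""
    materials = dict(MATERIALS) if materials is None else materials
    energies = np.geomspace(e_min_kev, e_max_kev, n_points)
    kn = klein_nishina_total(energies)
    scatter_frac = klein_nishina_mean_scatter_fraction(energies)
    pe_norm = _PE_ANCHOR * _PE_ANCHOR_E**3 / _PE_WATER_WEIGHT

    pe, inc, tr, dens = {}, {}, {}, {}
    for code, mat in materials.items():
        inc[code] = mat.electrons_per_gram() * kn
        pe[code] = pe_norm * mat.photoelectric_weight() / energies**3
        tr[code] = pe[code] + inc[code] * (1.0 - scatter_frac)
        dens[code] = mat.density
    return CrossSectionTable(energies, pe, inc, tr, dens)
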