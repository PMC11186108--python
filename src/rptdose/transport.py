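"""Voxel Monte Carlo photon transport with local beta deposition.

Analog photon transport over a material grid using Woodcock (delta)
tracking against the grid's majorant attenuation.  At real collisions,
photoelectric events deposit the full photon energy in the current voxel;
incoherent scatters sample the Klein-Nishina free-electron distribution
(Kahn's rejection method), deposit the electron energy locally and continue
the photon.  Photons terminate below a 10 keV cutoff (energy deposited
locally) or on grid exit (energy booked as escaped), so deposited + escaped
energy equals emitted energy exactly in every batch.

Scoring:

* per-voxel analog dose (deposited energy / voxel mass), Gy per history,
  with batch-statistics relative uncertainties;
* track-length fluence spectra at cubic scorer volumes (each Woodcock step
  segment crossing a scorer credits its chord length to the energy bin of
  the photon), and the derived collision-kerma dose to the scorer,
  Phi(E) * E * mu_tr/rho — the low-variance estimator used for probe doses;
* beta emissions are deposited as their expected value (the per-decay mean
  beta energy, apportioned over source voxels by activity): the beta range
  in water is below the grid spacing, so local deposition involves no
  stochastic transport and the expected-value tally is exact.

One decay is one history; each history draws one photon from the emission
lines with statistical weight equal to the total photon yield per decay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .attenuation import CrossSectionTable
from .grids import GridSpec, MaterialGrid, Volume
from .nuclide import NuclideData

__all__ = [
    "ScorerSpec",
    "FluenceSpectrum",
    "DoseGrid",
    "TransportResult",
    "SphereSource",
    "VoxelSource",
    "sample_emission",
    "run_dose",
    "mean_energy",
    "absolute_dose_map",
    "sample_klein_nishina",
    "first_collision_free_fraction",
]

_KEV_TO_J = 1.602176634e-16
_MEC2_KEV = 510.99895
DEFAULT_CUTOFF_KEV = 10.0


@dataclass(frozen=True)
class ScorerSpec:
    """Cubic fluence/dose scorer (probe TLD stand-in)."""

    center_mm: tuple[float, float, float]
    edge_mm: float = 5.0
    scorer_id: int = 0

    def __post_init__(self) -> None:
        if self.edge_mm <= 0:
            raise ValueError("scorer edge must be > 0")

    @property
    def volume_cm3(self) -> float:
        return (self.edge_mm / 10.0) ** 3


@dataclass
class FluenceSpectrum:
    """Binned track-length fluence at a scorer, cm^-2 per history."""

    bin_edges_kev: np.ndarray
    values: np.ndarray
    scorer_id: int = 0

    def __post_init__(self) -> None:
        self.bin_edges_kev = np.asarray(self.bin_edges_kev, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != len(self.bin_edges_kev) - 1:
            raise ValueError("values must have one entry per bin")
        if np.any(self.values < 0):
            raise ValueError("fluence values must be >= 0")

    @property
    def bin_centers_kev(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_kev[:-1] + self.bin_edges_kev[1:])


@dataclass
class DoseGrid:
    """Per-voxel dose with fractional statistical uncertainties."""

    grid: GridSpec
    dose: np.ndarray  # Gy/history or Gy
    rel_uncertainty: np.ndarray
    histories: int
    unit: str = "Gy/history"

    def __post_init__(self) -> None:
        if self.histories <= 0:
            raise ValueError("histories must be > 0")
        if np.any(self.dose < 0):
            raise ValueError("dose must be >= 0")

    def as_volume(self) -> Volume:
        return Volume(self.grid, self.dose, self.unit)


@dataclass
class TransportResult:
    dose: DoseGrid
    spectra: list[FluenceSpectrum]
    scorer_dose_per_history: np.ndarray  # Gy/history, track-length kerma
    scorer_dose_rel_unc: np.ndarray
    energy_balance: dict
    histories: int
    seed: int


# ---------------------------------------------------------------------------
# sources

@dataclass(frozen=True)
class SphereSource:
    """Uniform activity in an analytic sphere (idealized mode)."""

    center_mm: tuple[float, float, float]
    radius_mm: float

    def sample_positions(self, n: int, rng: np.random.Generator) -> np.ndarray:
        r = self.radius_mm * rng.random(n) ** (1.0 / 3.0)
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        return np.asarray(self.center_mm) + r[:, None] * v

    def voxel_fractions(self, grid: GridSpec, subsamples: int = 2) -> np.ndarray:
        offs = (np.arange(subsamples) + 0.5) / subsamples - 0.5
        frac = np.zeros(grid.shape, dtype=np.float64)
        cx, cy, cz = self.center_mm
        xs, ys, zs = (grid.voxel_centers(a) for a in range(3))
        for ox in offs:
            for oy in offs:
                for oz in offs:
                    d2 = (
                        (xs[:, None, None] + ox * grid.spacing[0] - cx) ** 2
                        + (ys[None, :, None] + oy * grid.spacing[1] - cy) ** 2
                        + (zs[None, None, :] + oz * grid.spacing[2] - cz) ** 2
                    )
                    frac += d2 <= self.radius_mm**2
        frac /= subsamples**3
        total = frac.sum()
        if total == 0:
            raise ValueError("sphere source does not intersect the grid")
        return frac / total


@dataclass
class VoxelSource:
    """Activity-map source (image mode): voxels sampled proportionally."""

    activity: Volume

    def __post_init__(self) -> None:
        if self.activity.unit != "Bq":
            raise ValueError("voxel source activity must be tagged 'Bq'")
        if self.activity.total() <= 0:
            raise ValueError("source has zero total activity")

    def voxel_fractions(self, grid: GridSpec, subsamples: int = 2) -> np.ndarray:
        if grid != self.activity.grid:
            raise ValueError("voxel source must live on the transport grid")
        return np.asarray(self.activity.values, dtype=np.float64) / self.activity.total()

    def sample_positions(self, n: int, rng: np.random.Generator) -> np.ndarray:
        grid = self.activity.grid
        p = np.asarray(self.activity.values, dtype=np.float64).ravel()
        nz = np.flatnonzero(p)
        flat = rng.choice(nz, size=n, p=p[nz] / p[nz].sum())
        idx = np.stack(np.unravel_index(flat, grid.shape), axis=1).astype(np.float64)
        idx += rng.random((n, 3)) - 0.5
        return grid.index_to_world(idx)


# ---------------------------------------------------------------------------
# emission sampling

def sample_emission(
    nuclide: NuclideData, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    """Sample photon energies and isotropic directions for ``n`` decays.

    Returns ``(energies_kev, directions, weight)`` where each history
    carries one photon of statistical weight = total photon yield.
    """
    if not nuclide.photon_lines:
        raise ValueError("nuclide has no photon emission lines")
    energies = np.array([e for e, _ in nuclide.photon_lines])
    yields = np.array([y for _, y in nuclide.photon_lines])
    total_yield = yields.sum()
    if total_yield <= 0:
        raise ValueError("total photon yield must be > 0")
    e = rng.choice(energies, size=n, p=yields / total_yield)
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return e, d, float(total_yield)


def sample_klein_nishina(
    energy_kev: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Kahn's rejection sampling of the Klein-Nishina distribution.

    Returns ``(cos_theta, e_ratio)`` with ``e_ratio = E'/E``.
    """
    e = np.asarray(energy_kev, dtype=np.float64)
    alpha = e / _MEC2_KEV
    n = e.shape[0]
    cos_t = np.empty(n)
    ratio = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        a = alpha[todo]
        r1, r2, r3 = rng.random((3, todo.size))
        branch1 = r1 <= (1 + 2 * a) / (9 + 2 * a)
        x = np.where(branch1, 1 + 2 * a * r2, (1 + 2 * a) / (1 + 2 * a * r2))
        ct = 1 - (x - 1) / a
        acc1 = r3 <= 4 * (1 / x - 1 / x**2)
        acc2 = r3 <= 0.5 * (ct**2 + 1 / x)
        accept = np.where(branch1, acc1, acc2)
        sel = todo[accept]
        cos_t[sel] = ct[accept]
        ratio[sel] = 1.0 / x[accept]
        todo = todo[~accept]
    return cos_t, ratio


def _rotate_directions(
    d: np.ndarray, cos_t: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Rotate unit vectors by polar angle theta and uniform azimuth."""
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t**2))
    phi = 2 * np.pi * rng.random(len(d))
    # orthonormal frame around d
    small = np.abs(d[:, 2]) < 0.99
    a = np.where(small[:, None], np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]))
    u = np.cross(a, d)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(d, u)
    return (
        cos_t[:, None] * d
        + sin_t[:, None] * (np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * v)
    )


# ---------------------------------------------------------------------------
# cross-section lookup tables for the tracking loop

class _MuLookup:
    """Linear-in-log-energy lookup of per-material coefficients."""

    def __init__(self, xs: CrossSectionTable, codes: list[int], n_grid: int = 512):
        self.log_e0 = math.log(xs.energies[0])
        self.log_e1 = math.log(xs.energies[-1])
        self.n = n_grid
        self.dlog = (self.log_e1 - self.log_e0) / (n_grid - 1)
        e = np.exp(self.log_e0 + self.dlog * np.arange(n_grid))
        max_code = max(codes)
        self.mu = np.zeros((max_code + 1, n_grid))
        self.pe_frac = np.zeros((max_code + 1, n_grid))
        self.mu_tr_rho = np.zeros((max_code + 1, n_grid))
        for c in codes:
            self.mu[c] = xs.mu_linear(c, e)
            self.pe_frac[c] = xs.pe_fraction(c, e)
            self.mu_tr_rho[c] = xs.mu_tr_over_rho(c, e)
        self.mu_maj = self.mu[codes].max(axis=0)

    def _findex(self, e_kev: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        f = (np.log(np.clip(e_kev, math.exp(self.log_e0), math.exp(self.log_e1))) - self.log_e0) / self.dlog
        i = np.clip(f.astype(np.int64), 0, self.n - 2)
        return i, f - i

    def majorant(self, e_kev: np.ndarray) -> np.ndarray:
        i, w = self._findex(e_kev)
        return self.mu_maj[i] * (1 - w) + self.mu_maj[i + 1] * w

    def local(self, table: np.ndarray, codes: np.ndarray, e_kev: np.ndarray) -> np.ndarray:
        i, w = self._findex(e_kev)
        return table[codes, i] * (1 - w) + table[codes, i + 1] * w


def _segment_lengths_in_boxes(
    pos: np.ndarray, dirs: np.ndarray, step: np.ndarray, lo: np.ndarray, hi: np.ndarray
) -> np.ndarray:
    """Chord length (mm) of segments [pos, pos + dirs*step] in each AABB.

    Returns array (n_boxes, n_segments)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / dirs  # inf where parallel
    t_lo = (lo[:, None, :] - pos[None, :, :]) * inv[None, :, :]
    t_hi = (hi[:, None, :] - pos[None, :, :]) * inv[None, :, :]
    t1 = np.minimum(t_lo, t_hi)
    t2 = np.maximum(t_lo, t_hi)
    # parallel axes: inside -> (-inf, inf), outside -> empty
    par = np.abs(dirs) < 1e-12
    if par.any():
        inside = (pos[None, :, :] >= lo[:, None, :]) & (pos[None, :, :] <= hi[:, None, :])
        t1 = np.where(par[None, :, :], np.where(inside, -np.inf, np.inf), t1)
        t2 = np.where(par[None, :, :], np.where(inside, np.inf, -np.inf), t2)
    t_enter = np.maximum(t1.max(axis=2), 0.0)
    t_exit = np.minimum(t2.min(axis=2), step[None, :])
    return np.maximum(0.0, t_exit - t_enter)


@dataclass
class _BatchTallies:
    dose_j: np.ndarray  # deposited energy per voxel, J-weighted (keV * weight)
    spectrum_cm: np.ndarray  # (n_scorer, n_bins) track length, cm * weight
    kerma: np.ndarray  # (n_scorer,) Gy * histories
    emitted_kev: float = 0.0
    deposited_kev: float = 0.0
    escaped_kev: float = 0.0


def _transport_photons(
    e0: np.ndarray,
    d0: np.ndarray,
    p0: np.ndarray,
    weight: float,
    mats_flat: np.ndarray,
    grid: GridSpec,
    lut: _MuLookup,
    scorer_lo: np.ndarray,
    scorer_hi: np.ndarray,
    scorer_codes: np.ndarray,
    scorer_volume_cm3: np.ndarray,
    bin_edges: np.ndarray,
    tallies: _BatchTallies,
    rng: np.random.Generator,
    cutoff_kev: float,
) -> None:
    """Track one chunk of photons to extinction, accumulating tallies."""
    origin = np.asarray(grid.origin)
    spacing = np.asarray(grid.spacing)
    shape = np.asarray(grid.shape)
    strides = np.array([grid.shape[1] * grid.shape[2], grid.shape[2], 1])
    bin_w = bin_edges[1] - bin_edges[0]
    n_bins = len(bin_edges) - 1

    e, d, p = e0.copy(), d0.copy(), p0.copy()
    tallies.emitted_kev += weight * float(e.sum())
    while e.size:
        mu_maj = lut.majorant(e)  # 1/cm
        step = -np.log(rng.random(e.size)) / mu_maj * 10.0  # mm
        if scorer_lo.size:
            seg = _segment_lengths_in_boxes(p, d, step, scorer_lo, scorer_hi)
            hit_s, hit_p = np.nonzero(seg > 0)
            if hit_s.size:
                seg_cm = seg[hit_s, hit_p] / 10.0 * weight
                bins = np.clip((e[hit_p] / bin_w).astype(np.int64), 0, n_bins - 1)
                np.add.at(tallies.spectrum_cm, (hit_s, bins), seg_cm)
                mu_tr = lut.local(lut.mu_tr_rho, scorer_codes[hit_s], e[hit_p])
                np.add.at(
                    tallies.kerma,
                    hit_s,
                    seg_cm
                    / scorer_volume_cm3[hit_s]
                    * e[hit_p]
                    * _KEV_TO_J
                    * mu_tr
                    * 1000.0,
                )
        p = p + d * step[:, None]
        idx = np.floor((p - origin) / spacing + 0.5).astype(np.int64)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        if not inside.all():
            tallies.escaped_kev += weight * float(e[~inside].sum())
            e, d, p, idx = e[inside], d[inside], p[inside], idx[inside]
            if not e.size:
                break
        flat = idx @ strides
        codes = mats_flat[flat]
        mu_loc = lut.local(lut.mu, codes, e)
        real = rng.random(e.size) < mu_loc / lut.majorant(e)
        if real.any():
            r_flat = flat[real]
            r_codes = codes[real]
            r_e = e[real]
            pe = rng.random(r_e.size) < lut.local(lut.pe_frac, r_codes, r_e)
            dep = np.where(pe, r_e, 0.0)
            # Compton on the rest
            if (~pe).any():
                c_idx = np.flatnonzero(real)[~pe]
                cos_t, ratio = sample_klein_nishina(e[c_idx], rng)
                e_new = e[c_idx] * ratio
                dep[~pe] = e[c_idx] - e_new
                below = e_new < cutoff_kev
                dep[np.flatnonzero(~pe)[below]] += e_new[below]
                d[c_idx] = _rotate_directions(d[c_idx], cos_t, rng)
                e[c_idx] = np.where(below, 0.0, e_new)
            np.add.at(tallies.dose_j, r_flat, weight * dep)
            tallies.deposited_kev += weight * float(dep.sum())
            # photoelectric and cutoff photons die
            dead = np.zeros(e.size, dtype=bool)
            dead[np.flatnonzero(real)[pe]] = True
            dead |= e == 0.0
            if dead.any():
                keep = ~dead
                e, d, p = e[keep], d[keep], p[keep]


def run_dose(
    source,
    materials: MaterialGrid,
    xs: CrossSectionTable,
    scorers: list[ScorerSpec],
    histories: int,
    seed: int,
    nuclide: NuclideData,
    batches: int = 10,
    cutoff_kev: float = DEFAULT_CUTOFF_KEV,
    include_photons: bool = True,
    include_betas: bool = True,
    chunk_size: int = 400_000,
    spectrum_bin_kev: float = 5.0,
    spectrum_max_kev: float = 730.0,
) -> TransportResult:
    """Run the Monte Carlo dose calculation.

    ``source`` is a :class:`SphereSource` (idealized mode) or
    :class:`VoxelSource` (image mode) co-registered with ``materials``.
    One history is one decay; results are normalized per history.
    """
    if histories <= 0 or batches <= 0:
        raise ValueError("histories and batches must be > 0")
    grid = materials.grid
    mats_flat = np.ascontiguousarray(materials.material_index.ravel().astype(np.int64))
    codes = sorted(materials.densities)
    lut = _MuLookup(xs, codes)

    # per-voxel mass in kg
    dens = np.array([materials.densities.get(c, 0.0) for c in range(max(codes) + 1)])
    voxel_cm3 = grid.voxel_volume_mm3 / 1000.0
    mass_kg = dens[mats_flat] * voxel_cm3 / 1000.0  # g -> kg

    n_bins = int(round(spectrum_max_kev / spectrum_bin_kev))
    bin_edges = np.linspace(0.0, spectrum_max_kev, n_bins + 1)
    max_line = max((e for e, _ in nuclide.photon_lines), default=0.0)
    if max_line > spectrum_max_kev:
        raise ValueError("spectrum bins do not cover all emission lines")

    scorer_lo = np.array([np.asarray(s.center_mm) - 0.5 * s.edge_mm for s in scorers])
    scorer_hi = np.array([np.asarray(s.center_mm) + 0.5 * s.edge_mm for s in scorers])
    scorer_vol = np.array([s.volume_cm3 for s in scorers])
    if scorers:
        s_idx = np.floor(
            (np.array([s.center_mm for s in scorers]) - np.asarray(grid.origin))
            / np.asarray(grid.spacing)
            + 0.5
        ).astype(np.int64)
        scorer_codes = mats_flat[s_idx @ np.array([grid.shape[1] * grid.shape[2], grid.shape[2], 1])]
    else:
        scorer_codes = np.zeros(0, dtype=np.int64)

    # expected-value beta dose per history (Gy/history), identical every batch
    beta_dose_ph = np.zeros(grid.n_voxels)
    if include_betas and nuclide.beta_mean_energy_kev > 0:
        src_frac = source.voxel_fractions(grid).ravel()
        with np.errstate(divide="ignore", invalid="ignore"):
            beta_dose_ph = np.where(
                mass_kg > 0, src_frac * nuclide.beta_mean_energy_kev * _KEV_TO_J / mass_kg, 0.0
            )

    per_batch = [histories // batches + (1 if b < histories % batches else 0) for b in range(batches)]
    dose_sum = np.zeros(grid.n_voxels)
    dose_sumsq = np.zeros(grid.n_voxels)
    kerma_batches = np.zeros((batches, len(scorers)))
    spectrum_total = np.zeros((len(scorers), n_bins))
    balance = {"emitted_kev": [], "deposited_kev": [], "escaped_kev": []}

    ss = np.random.SeedSequence(seed)
    batch_seeds = ss.spawn(batches)
    for b, (n_b, bs) in enumerate(zip(per_batch, batch_seeds)):
        rng = np.random.default_rng(bs)
        tallies = _BatchTallies(
            dose_j=np.zeros(grid.n_voxels),
            spectrum_cm=np.zeros((len(scorers), n_bins)),
            kerma=np.zeros(len(scorers)),
        )
        if include_photons and nuclide.photon_lines:
            remaining = n_b
            while remaining > 0:
                m = min(chunk_size, remaining)
                remaining -= m
                energies, dirs, weight = sample_emission(nuclide, m, rng)
                pos = source.sample_positions(m, rng)
                _transport_photons(
                    energies, dirs, pos, weight, mats_flat, grid, lut,
                    scorer_lo, scorer_hi, scorer_codes, scorer_vol,
                    bin_edges, tallies, rng, cutoff_kev,
                )
        with np.errstate(divide="ignore", invalid="ignore"):
            dose_b = np.where(mass_kg > 0, tallies.dose_j * _KEV_TO_J / mass_kg, 0.0) / n_b
        dose_b += beta_dose_ph
        dose_sum += dose_b
        dose_sumsq += dose_b**2
        kerma_batches[b] = tallies.kerma / n_b
        spectrum_total += tallies.spectrum_cm / n_b
        beta_kev = (
            n_b * nuclide.beta_mean_energy_kev if include_betas else 0.0
        )
        balance["emitted_kev"].append(tallies.emitted_kev + beta_kev)
        balance["deposited_kev"].append(tallies.deposited_kev + beta_kev)
        balance["escaped_kev"].append(tallies.escaped_kev)

    dose_mean = dose_sum / batches
    if batches > 1:
        var = np.maximum(dose_sumsq / batches - dose_mean**2, 0.0) * batches / (batches - 1)
        sem = np.sqrt(var / batches)
    else:
        sem = np.zeros_like(dose_mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(dose_mean > 0, sem / dose_mean, 0.0)

    kerma_mean = kerma_batches.mean(axis=0)
    if batches > 1 and len(scorers):
        kerma_sem = kerma_batches.std(axis=0, ddof=1) / math.sqrt(batches)
        with np.errstate(divide="ignore", invalid="ignore"):
            kerma_rel = np.where(kerma_mean > 0, kerma_sem / kerma_mean, 0.0)
    else:
        kerma_rel = np.zeros(len(scorers))

    spectra = [
        FluenceSpectrum(bin_edges, spectrum_total[i] / batches / s.volume_cm3, s.scorer_id)
        for i, s in enumerate(scorers)
    ]
    dose_grid = DoseGrid(
        grid,
        dose_mean.reshape(grid.shape),
        rel.reshape(grid.shape),
        histories,
        "Gy/history",
    )
    return TransportResult(
        dose=dose_grid,
        spectra=spectra,
        scorer_dose_per_history=kerma_mean,
        scorer_dose_rel_unc=kerma_rel,
        energy_balance=balance,
        histories=histories,
        seed=seed,
    )


def mean_energy(spectrum: FluenceSpectrum) -> float:
    """Fluence-weighted mean energy of a spectrum, keV."""
    total = spectrum.values.sum()
    if total <= 0:
        raise ValueError("spectrum is empty")
    return float((spectrum.values * spectrum.bin_centers_kev).sum() / total)


def absolute_dose_map(per_history: DoseGrid, a_tilde_bq_s: float) -> DoseGrid:
    """Scale a per-history dose map to absolute Gy: D = A_tilde * D_history."""
    if a_tilde_bq_s < 0:
        raise ValueError("cumulated activity must be >= 0")
    return DoseGrid(
        per_history.grid,
        per_history.dose * a_tilde_bq_s,
        per_history.rel_uncertainty.copy(),
        per_history.histories,
        "Gy",
    )


def first_collision_free_fraction(
    materials: MaterialGrid,
    xs: CrossSectionTable,
    start_mm: np.ndarray,
    direction: np.ndarray,
    energy_kev: float,
    depth_mm: float,
    n_histories: int,
    seed: int,
) -> float:
    """Fraction of photons whose first *real* collision lies beyond
    ``depth_mm`` along a pencil beam, sampled with the same Woodcock
    tracking used by the dose engine (transmission validation)."""
    grid = materials.grid
    mats_flat = materials.material_index.ravel().astype(np.int64)
    codes = sorted(materials.densities)
    lut = _MuLookup(xs, codes)
    rng = np.random.default_rng(seed)
    origin = np.asarray(grid.origin)
    spacing = np.asarray(grid.spacing)
    shape = np.asarray(grid.shape)
    strides = np.array([grid.shape[1] * grid.shape[2], grid.shape[2], 1])

    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    pos = np.tile(np.asarray(start_mm, dtype=float), (n_histories, 1))
    path = np.zeros(n_histories)
    alive = np.ones(n_histories, dtype=bool)
    survived = np.zeros(n_histories, dtype=bool)
    e = np.full(n_histories, float(energy_kev))
    while alive.any():
        ii = np.flatnonzero(alive)
        step = -np.log(rng.random(ii.size)) / lut.majorant(e[ii]) * 10.0
        path[ii] += step
        pos[ii] += d * step[:, None]
        past = path[ii] >= depth_mm
        survived[ii[past]] = True
        alive[ii[past]] = False
        ii = ii[~past]
        if not ii.size:
            break
        idx = np.floor((pos[ii] - origin) / spacing + 0.5).astype(np.int64)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        # leaving the grid before depth counts as uncollided only if past depth
        alive[ii[~inside]] = False
        ii = ii[inside]
        idx = idx[inside]
        if not ii.size:
            continue
        codes_i = mats_flat[idx @ strides]
        mu_loc = lut.local(lut.mu, codes_i, e[ii])
        real = rng.random(ii.size) < mu_loc / lut.majorant(e[ii])
        alive[ii[real]] = False
    return float(survived.sum()) / n_histories
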