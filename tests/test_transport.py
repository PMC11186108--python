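"""Monte Carlo engine: samplers, tracking oracles, energy bookkeeping."""

import numpy as np
import pytest
from scipy import integrate

from rptdose.attenuation import klein_nishina_mean_scatter_fraction
from rptdose.grids import GridSpec, MaterialGrid, Volume
from rptdose.materials import AIR, WATER
from rptdose.nuclide import NuclideData
from rptdose.transport import (
    DoseGrid,
    FluenceSpectrum,
    ScorerSpec,
    SphereSource,
    VoxelSource,
    absolute_dose_map,
    first_collision_free_fraction,
    mean_energy,
    run_dose,
    sample_emission,
    sample_klein_nishina,
    run_dose as _run_dose,
)
from rptdose.transport import _segment_lengths_in_boxes

_MEC2 = 510.99895

WATER_BOX = GridSpec.centered((20, 20, 20), (10.0, 10.0, 10.0))


def water_box_materials(grid=WATER_BOX):
    return MaterialGrid(
        grid, np.full(grid.shape, WATER.code, dtype=np.int8),
        {AIR.code: AIR.density, WATER.code: WATER.density},
    )


def single_line_nuclide(energy=364.489, beta=0.0):
    return NuclideData("test", 8.0, ((energy, 1.0),), beta)


class TestEmissionSampling:
    def test_single_line_all_photons_at_line(self, rng):
        e, d, w = sample_emission(single_line_nuclide(500.0), 1000, rng)
        assert np.all(e == 500.0)
        assert w == 1.0

    def test_i131_line_frequencies_within_3sigma(self, i131, rng):
        """Empirical draw frequency of the 364.5 keV line vs its yield."""
        n = 10**5
        e, _, w = sample_emission(i131, n, rng)
        p = dict(i131.photon_lines)[364.489] / i131.total_photon_yield
        k = (e == 364.489).sum()
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(k - n * p) < 3.5 * sigma

    def test_directions_isotropic(self, i131, rng):
        _, d, _ = sample_emission(i131, 10**5, rng)
        np.testing.assert_allclose(np.linalg.norm(d, axis=1), 1.0, rtol=1e-12)
        assert np.all(np.abs(d.mean(axis=0)) < 0.01)


class TestKleinNishina:
    def test_mean_scattered_energy_matches_analytic(self, rng):
        """Kahn sampler mean E'/E at 364.5 keV vs quadrature, 1e6 samples."""
        e = np.full(10**6, 364.489)
        _, ratio = sample_klein_nishina(e, rng)
        analytic = klein_nishina_mean_scatter_fraction(364.489)
        assert ratio.mean() == pytest.approx(analytic, rel=0.005)

    def test_distribution_matches_differential_shape(self, rng):
        """Sampled cos(theta) histogram vs the analytic angular density."""
        e_kev = 200.0
        k = e_kev / _MEC2
        cos_t, _ = sample_klein_nishina(np.full(200_000, e_kev), rng)

        def dsigma(c):
            r = 1.0 / (1.0 + k * (1.0 - c))
            return r**2 * (r + 1.0 / r - (1.0 - c**2))

        norm, _ = integrate.quad(dsigma, -1, 1)
        hist, edges = np.histogram(cos_t, bins=20, range=(-1, 1), density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        expected = np.array([dsigma(c) for c in centers]) / norm
        np.testing.assert_allclose(hist, expected, rtol=0.05)

    def test_ratio_bounded_by_kinematics(self, rng):
        e = np.full(10**4, 364.489)
        _, ratio = sample_klein_nishina(e, rng)
        k = 364.489 / _MEC2
        assert ratio.max() <= 1.0 + 1e-12
        assert ratio.min() >= 1.0 / (1 + 2 * k) - 1e-12


class TestTransmissionOracles:
    def test_uniform_water_slab_vs_analytic(self, xs_table):
        """Uncollided fraction through 10 cm water vs exp(-mu d), 3 sigma."""
        mats = water_box_materials()
        mu = xs_table.mu_linear(WATER.code, np.array([364.489]))[0]
        depth = 100.0
        n = 10**5
        f = first_collision_free_fraction(
            mats, xs_table, np.array([0.0, 0.0, -95.0]), np.array([0, 0, 1.0]),
            364.489, depth, n, seed=42,
        )
        expected = np.exp(-mu * depth / 10.0)
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert abs(f - expected) < 3.5 * sigma

    def test_heterogeneous_slabs_vs_ray_march_oracle(self, xs_table):
        """Woodcock tracking vs an independent voxel-by-voxel ray march on a
        heterogeneous 5^3 grid (air/water/acrylic slabs)."""
        grid = GridSpec.centered((5, 5, 5), (8.0, 8.0, 8.0))
        codes = np.ones(grid.shape, dtype=np.int8) * WATER.code
        codes[:, :, 0] = AIR.code
        codes[:, :, 2] = 2  # acrylic
        codes[:, :, 4] = AIR.code
        mats = MaterialGrid(grid, codes, {0: AIR.density, 1: 1.0, 2: 1.19})
        e_kev = 284.305
        start = np.array([0.0, 0.0, -19.9])
        depth = 39.0

        # oracle: march the ray voxel by voxel, accumulate mu * d analytically
        n_steps = 4000
        zs = start[2] + (np.arange(n_steps) + 0.5) * depth / n_steps
        k_idx = np.floor((zs - grid.origin[2]) / grid.spacing[2] + 0.5).astype(int)
        k_idx = np.clip(k_idx, 0, grid.shape[2] - 1)
        mu_per_code = {
            c: xs_table.mu_linear(c, np.array([e_kev]))[0] for c in (0, 1, 2)
        }
        optical = sum(mu_per_code[codes[2, 2, k]] for k in k_idx) * (depth / n_steps) / 10.0
        expected = np.exp(-optical)

        n = 10**5
        f = first_collision_free_fraction(
            mats, xs_table, start, np.array([0, 0, 1.0]), e_kev, depth, n, seed=7
        )
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert abs(f - expected) < 3.5 * sigma


class TestRunDose:
    def test_seeded_determinism(self, xs_table, i131):
        mats = water_box_materials()
        src = SphereSource((0.0, 0.0, 0.0), 15.0)
        scorers = [ScorerSpec((50.0, 0.0, 0.0), 5.0, 1)]
        a = run_dose(src, mats, xs_table, scorers, 20_000, seed=9, nuclide=i131, batches=2)
        b = run_dose(src, mats, xs_table, scorers, 20_000, seed=9, nuclide=i131, batches=2)
        np.testing.assert_array_equal(a.dose.dose, b.dose.dose)
        np.testing.assert_array_equal(
            a.scorer_dose_per_history, b.scorer_dose_per_history
        )

    @pytest.mark.parametrize("mode", ["sphere", "voxel"])
    def test_energy_conservation_exact_per_batch(self, xs_table, i131, mode):
        """Deposited + escaped equals emitted in every batch, both source types."""
        mats = water_box_materials()
        if mode == "sphere":
            src = SphereSource((0.0, 0.0, 0.0), 20.0)
        else:
            act = np.zeros(WATER_BOX.shape)
            act[8:12, 8:12, 8:12] = 1.0
            src = VoxelSource(Volume(WATER_BOX, act, "Bq"))
        res = run_dose(src, mats, xs_table, [], 30_000, seed=3, nuclide=i131, batches=3)
        em = np.array(res.energy_balance["emitted_kev"])
        de = np.array(res.energy_balance["deposited_kev"])
        es = np.array(res.energy_balance["escaped_kev"])
        np.testing.assert_allclose(de + es, em, rtol=1e-9)

    def test_beta_equilibrium_closed_form(self, xs_table):
        """Uniform beta-only source in water: dose = conc x E_mean / rho."""
        grid = GridSpec.centered((12, 12, 12), (10.0, 10.0, 10.0))
        mats = water_box_materials(grid)
        act = Volume(grid, np.ones(grid.shape), "Bq")  # uniform concentration
        nuc = NuclideData("beta-only", 8.0, (), 191.6)
        res = run_dose(
            VoxelSource(act), mats, xs_table, [], 10_000, seed=1, nuclide=nuc,
            batches=2, include_photons=False,
        )
        kev_to_j = 1.602176634e-16
        n_vox = grid.n_voxels
        mass_kg = WATER.density * grid.voxel_volume_mm3 / 1000.0 / 1000.0
        expected = (1.0 / n_vox) * 191.6 * kev_to_j / mass_kg
        interior = res.dose.dose[2:-2, 2:-2, 2:-2]
        np.testing.assert_allclose(interior, expected, rtol=0.005)

    def test_rel_uncertainty_scales_inverse_sqrt(self, xs_table):
        """Batch-estimated uncertainty falls as N^-0.5 (log-log slope)."""
        mats = water_box_materials()
        src = SphereSource((0.0, 0.0, 0.0), 15.0)
        scorers = [ScorerSpec((40.0, 0.0, 0.0), 10.0, 1)]
        nuc = single_line_nuclide()
        ns = [8_000, 32_000, 128_000, 512_000]
        uncs = []
        for n in ns:
            res = run_dose(src, mats, xs_table, scorers, n, seed=21, nuclide=nuc, batches=10)
            uncs.append(res.scorer_dose_rel_unc[0])
        slope = np.polyfit(np.log(ns), np.log(uncs), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)

    def test_inverse_square_fluence_in_transparent_medium(self, xs_table, i131):
        """Point-like source in air: scorer fluence x 4 pi r^2 constant."""
        grid = GridSpec.centered((40, 40, 40), (10.0, 10.0, 10.0))
        mats = MaterialGrid(
            grid, np.full(grid.shape, AIR.code, dtype=np.int8),
            {AIR.code: AIR.density, WATER.code: WATER.density},
        )
        src = SphereSource((0.0, 0.0, 0.0), 0.5)
        scorers = [
            ScorerSpec((60.0, 0.0, 0.0), 6.0, 1),
            ScorerSpec((120.0, 0.0, 0.0), 6.0, 2),
        ]
        nuc = single_line_nuclide()
        res = run_dose(src, mats, xs_table, scorers, 400_000, seed=11, nuclide=nuc, batches=10)
        phi = [s.values.sum() for s in res.spectra]
        scaled = [p * 4 * np.pi * r**2 for p, r in zip(phi, (6.0, 12.0))]  # r in cm
        # combined MC noise on each scaled flux
        rel = np.hypot(*res.scorer_dose_rel_unc)
        assert abs(scaled[0] - scaled[1]) / scaled[0] < max(3.5 * rel, 0.03)

    def test_zero_activity_rejected(self, xs_table, i131):
        with pytest.raises(ValueError):
            VoxelSource(Volume(WATER_BOX, np.zeros(WATER_BOX.shape), "Bq"))


class TestScorerGeometry:
    def test_chord_length_through_centered_box(self):
        """Axis-aligned segment through a 5 mm cube scores the full edge."""
        lo = np.array([[-2.5, -2.5, -2.5]])
        hi = np.array([[2.5, 2.5, 2.5]])
        pos = np.array([[0.0, 0.0, -50.0]])
        dirs = np.array([[0.0, 0.0, 1.0]])
        seg = _segment_lengths_in_boxes(pos, dirs, np.array([100.0]), lo, hi)
        assert seg[0, 0] == pytest.approx(5.0)

    def test_miss_scores_zero(self):
        lo = np.array([[-2.5, -2.5, -2.5]])
        hi = np.array([[2.5, 2.5, 2.5]])
        pos = np.array([[10.0, 0.0, -50.0]])
        dirs = np.array([[0.0, 0.0, 1.0]])
        seg = _segment_lengths_in_boxes(pos, dirs, np.array([100.0]), lo, hi)
        assert seg[0, 0] == 0.0

    def test_oblique_chord(self):
        """Diagonal crossing of a cube: length = edge * sqrt(3)."""
        lo = np.array([[-2.5, -2.5, -2.5]])
        hi = np.array([[2.5, 2.5, 2.5]])
        d = np.ones(3) / np.sqrt(3.0)
        pos = -d * 50.0
        seg = _segment_lengths_in_boxes(
            pos[None, :], d[None, :], np.array([100.0]), lo, hi
        )
        assert seg[0, 0] == pytest.approx(5.0 * np.sqrt(3.0))


class TestSpectrumReduction:
    def test_mean_energy_single_bin(self):
        edges = np.linspace(0, 730, 147)
        vals = np.zeros(146)
        vals[72] = 3.0  # bin center 362.5
        s = FluenceSpectrum(edges, vals, 1)
        assert mean_energy(s) == pytest.approx(0.5 * (edges[72] + edges[73]))

    def test_mean_energy_two_equal_bins_is_midpoint(self):
        edges = np.linspace(0, 730, 147)
        vals = np.zeros(146)
        vals[20] = 1.0
        vals[40] = 1.0
        s = FluenceSpectrum(edges, vals, 1)
        mid = 0.5 * (s.bin_centers_kev[20] + s.bin_centers_kev[40])
        assert mean_energy(s) == pytest.approx(mid)

    def test_empty_spectrum_rejected(self):
        edges = np.linspace(0, 730, 147)
        with pytest.raises(ValueError):
            mean_energy(FluenceSpectrum(edges, np.zeros(146), 1))


class TestAbsoluteDoseMap:
    def test_zero_cumulated_activity(self):
        g = GridSpec((2, 2, 2), (1, 1, 1))
        d = DoseGrid(g, np.ones(g.shape), np.zeros(g.shape), 10)
        out = absolute_dose_map(d, 0.0)
        assert out.dose.sum() == 0.0 and out.unit == "Gy"

    def test_linearity_and_table_scale(self):
        g = GridSpec((2, 2, 2), (1, 1, 1))
        d = DoseGrid(g, np.full(g.shape, 1e-15), np.zeros(g.shape), 10)
        out = absolute_dose_map(d, 5.737e14)
        np.testing.assert_allclose(out.dose, 0.5737)
        out2 = absolute_dose_map(d, 2 * 5.737e14)
        np.testing.assert_allclose(out2.dose, 2 * out.dose)
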