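"""End-to-end pipeline driver.

Chains phantom construction, synthetic SPECT/CT, calibration, recovery-
coefficient quantification, Monte Carlo dose in both modes (idealized
stylized source and image-based), synthetic TLD readings with their
reduction, and the per-probe agreement report.  Every stage's seed derives
deterministically from the single run seed; rerunning an identical
configuration reproduces all stochastic outputs bit-identically.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from . import __version__
from .attenuation import build_table
from .config import RunConfig
from .io import write_manifest, write_volume
from .nuclide import (
    AdministrationRecord,
    activity_at,
    integrated_activity,
    load_i131,
)
from .phantom import build_phantom, sphere_voi_mask, voxelize, voxelize_activity
from .quantify import (
    RecoveryCoefficient,
    counts_to_activity,
    estimate_calibration_factor,
    density_to_material,
    hu_to_density,
    mask_background,
    percent_vs_administered,
    apply_recovery_coefficient,
    rescale_voi,
    resample_to_grid,
)
from .report import ProbeComparison, agreement_report
from .spect import (
    ScannerModel,
    calibration_scan,
    measure_recovery_coefficient,
    simulate_ct,
    simulate_spect,
)
from .tld import (
    CalibrationFit,
    TLDGroup,
    apply_corrections,
    combine_uncertainty,
    fit_calibration,
    load_default_response_curve,
    reduce_probe,
)
from .transport import (
    ScorerSpec,
    SphereSource,
    VoxelSource,
    absolute_dose_map,
    mean_energy,
    run_dose,
)

__all__ = ["PipelineResult", "run_pipeline", "make_fixtures"]


@dataclass
class PipelineResult:
    manifest: dict
    table: "object"  # AgreementTable
    out_dir: Path


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def synthesize_tld_readings(
    dose_gy: float,
    mean_energy_kev: float,
    curve,
    cfg_tld,
    rng: np.random.Generator,
) -> np.ndarray:
    """Raw chip signals a reader would record for a probe at this dose.

    Signal = dose x reader gain x relative energy response, with
    multiplicative chip-to-chip repeatability noise.
    """
    resp = curve.response(mean_energy_kev)
    noise = 1.0 + cfg_tld.repeatability_pct / 100.0 * rng.standard_normal(
        cfg_tld.chips_per_probe
    )
    return dose_gy * cfg_tld.gain_signal_per_gy * resp * noise


def _calibrate_synthetic_reader(cfg_tld, curve, rng: np.random.Generator) -> CalibrationFit:
    """Calibration exposure of chips at the calibration beam quality."""
    signals, doses = [], []
    resp = curve.response(cfg_tld.calibration_energy_kev)
    for d in cfg_tld.calibration_doses_gy:
        noise = 1.0 + cfg_tld.repeatability_pct / 100.0 * rng.standard_normal(
            cfg_tld.chips_per_probe
        )
        signals.extend(d * cfg_tld.gain_signal_per_gy * resp * noise)
        doses.extend([d] * cfg_tld.chips_per_probe)
    return fit_calibration(signals, doses)


def run_pipeline(config: RunConfig) -> PipelineResult:
    config.validate()
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    timings: dict[str, float] = {}
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": config.to_dict(),
    }

    nuclide = load_i131()
    lam = np.log(2.0) / config.half_life_days
    admin = config.admin

    # --- phantom ----------------------------------------------------------
    t = time.time()
    geometry = build_phantom(config.phantom)
    a_scan = activity_at(admin, lam, admin.t_scan_days)
    # ground-truth activity at scan time, rasterized directly on the SPECT grid
    truth_spect = voxelize_activity(
        geometry, config.scanner.spect_grid, subsamples=4, total_activity_bq=a_scan
    )
    mat_truth, _ = voxelize(
        geometry,
        config.scanner.ct_grid,
        subsamples=config.transport.voxelize_subsamples,
    )
    timings["phantom_s"] = time.time() - t

    # --- synthetic acquisition -------------------------------------------
    t = time.time()
    scanner = ScannerModel(
        psf_fwhm_mm=config.scanner.psf_fwhm_mm,
        sensitivity_cps_per_bq=config.scanner.sensitivity_cps_per_bq,
        scan_duration_s=config.scanner.scan_duration_s,
        spect_grid=config.scanner.spect_grid,
        ct_grid=config.scanner.ct_grid,
        noise=config.scanner.noise,
        seed=seeds[0],
    )
    counts = simulate_spect(truth_spect, scanner)
    ct = simulate_ct(mat_truth, scanner)
    cal_scanner = ScannerModel(
        psf_fwhm_mm=scanner.psf_fwhm_mm,
        sensitivity_cps_per_bq=scanner.sensitivity_cps_per_bq,
        scan_duration_s=scanner.scan_duration_s,
        spect_grid=scanner.spect_grid,
        ct_grid=scanner.ct_grid,
        noise=scanner.noise,
        seed=seeds[1],
    )
    cal_counts, cal_truth = calibration_scan(
        config.calibration.cylinder_volume_l,
        config.calibration.uniform_conc_bq_ml,
        cal_scanner,
    )
    timings["synthesis_s"] = time.time() - t

    # --- quantification ---------------------------------------------------
    t = time.time()
    cf = estimate_calibration_factor(cal_counts, cal_truth)
    rc_value = measure_recovery_coefficient(config.phantom.sphere_volume_ml, scanner)
    rc = RecoveryCoefficient(rc_value, config.phantom.sphere_volume_ml)
    activity_img = counts_to_activity(counts, cf)
    voi_spect = sphere_voi_mask(geometry, scanner.spect_grid)
    masked, removed_fraction = mask_background(activity_img, voi_spect)
    conc = masked.to_concentration()
    mean_conc_uncorr = float(conc.values[voi_spect].mean())
    mean_conc_corr = apply_recovery_coefficient(mean_conc_uncorr, rc)
    corrected = rescale_voi(masked, voi_spect, rc)
    voi_fine = sphere_voi_mask(geometry, scanner.ct_grid)
    act_fine, resample_change = resample_to_grid(
        corrected, scanner.ct_grid, voi_masks=(voi_spect, voi_fine)
    )
    pct_uncorr = percent_vs_administered(
        mean_conc_uncorr, admin, nuclide, config.phantom.sphere_volume_ml
    )
    pct_corr = percent_vs_administered(
        mean_conc_corr, admin, nuclide, config.phantom.sphere_volume_ml
    )
    density = hu_to_density(ct)
    mat_image = density_to_material(density)
    timings["quantification_s"] = time.time() - t

    # --- Monte Carlo dose, both modes ------------------------------------
    xs = build_table()
    scorers = [
        ScorerSpec(tuple(p), 5.0, i + 1)
        for i, p in enumerate(config.phantom.probe_positions_mm)
    ]
    t = time.time()
    ideal_src = SphereSource(
        tuple(config.phantom.sphere_center_mm), geometry.sphere_radius_mm
    )
    res_ideal = run_dose(
        ideal_src, mat_truth, xs, scorers,
        histories=config.transport.histories_ideal,
        seed=seeds[2], nuclide=nuclide,
        batches=config.transport.batches,
        cutoff_kev=config.transport.cutoff_kev,
    )
    timings["dose_ideal_s"] = time.time() - t
    t = time.time()
    res_image = run_dose(
        VoxelSource(act_fine), mat_image, xs, scorers,
        histories=config.transport.histories_image,
        seed=seeds[3], nuclide=nuclide,
        batches=config.transport.batches,
        cutoff_kev=config.transport.cutoff_kev,
    )
    timings["dose_image_s"] = time.time() - t

    # cumulated activities: idealized mode from the administration record;
    # image mode from the quantified sphere activity (corrected mean
    # concentration x known sphere volume) decay-corrected to time zero.
    # The activity map itself only supplies the spatial distribution (the
    # per-history dose is normalized per decay).
    a_tilde_ideal = integrated_activity(admin, lam).a_tilde_bq_s
    a_scan_image = mean_conc_corr * config.phantom.sphere_volume_ml
    a0_image = a_scan_image * float(np.exp(lam * admin.t_scan_days))
    a_tilde_image = integrated_activity(
        AdministrationRecord(a0_image, admin.t_exposed_days, admin.t_scan_days), lam
    ).a_tilde_bq_s

    dose_ideal_abs = absolute_dose_map(res_ideal.dose, a_tilde_ideal)
    dose_image_abs = absolute_dose_map(res_image.dose, a_tilde_image)
    probe_dose_ideal = res_ideal.scorer_dose_per_history * a_tilde_ideal
    probe_dose_image = res_image.scorer_dose_per_history * a_tilde_image
    mean_energies = [mean_energy(s) for s in res_ideal.spectra]

    # --- synthetic TLD measurement and reduction --------------------------
    t = time.time()
    curve = load_default_response_curve(config.tld.response_curve_csv)
    tld_rng = np.random.default_rng(seeds[4])
    calibration = _calibrate_synthetic_reader(config.tld, curve, tld_rng)
    groups = []
    for i, (d_true, e_mean) in enumerate(zip(probe_dose_ideal, mean_energies)):
        readings = synthesize_tld_readings(d_true, e_mean, curve, config.tld, tld_rng)
        g = TLDGroup(i + 1, readings, calibration, e_mean)
        apply_corrections(g, curve, config.tld.calibration_energy_kev)
        groups.append(g)
    measured = [reduce_probe(g) for g in groups]
    timings["tld_s"] = time.time() - t

    # --- agreement report -------------------------------------------------
    budget = combine_uncertainty(
        config.tld.budget_components,
        k=config.tld.coverage_k,
        conservative_override_percent=config.tld.conservative_override_percent,
    )
    rows = [
        ProbeComparison(
            probe_id=i + 1,
            measured_gy=measured[i][0],
            measured_sd_pct=measured[i][1],
            image_gy=float(probe_dose_image[i]),
            image_rel_unc=float(res_image.scorer_dose_rel_unc[i]),
            ideal_gy=float(probe_dose_ideal[i]),
            ideal_rel_unc=float(res_ideal.scorer_dose_rel_unc[i]),
        )
        for i in range(len(scorers))
    ]
    table = agreement_report(rows, budget)

    manifest.update(
        {
            "calibration_factor_bq_per_count": cf.value_bq_per_count,
            "recovery_coefficient": rc.value,
            "background_removed_fraction": removed_fraction,
            "mean_conc_uncorrected_mbq_ml": mean_conc_uncorr / 1e6,
            "mean_conc_corrected_mbq_ml": mean_conc_corr / 1e6,
            "pct_vs_administered_uncorrected": pct_uncorr,
            "pct_vs_administered_corrected": pct_corr,
            "resample_voi_mean_rel_change": resample_change,
            "a_tilde_ideal_bq_s": a_tilde_ideal,
            "a_tilde_image_bq_s": a_tilde_image,
            "probe_mean_energies_kev": mean_energies,
            "probe_dose_ideal_gy": list(probe_dose_ideal),
            "probe_dose_image_gy": list(probe_dose_image),
            "probe_dose_measured_gy": [m[0] for m in measured],
            "probe_measured_sd_pct": [m[1] for m in measured],
            "ideal_mc_rel_unc": list(res_ideal.scorer_dose_rel_unc),
            "image_mc_rel_unc": list(res_image.scorer_dose_rel_unc),
            "outlier_flags": [g.outlier_flags.tolist() for g in groups],
            "budget_combined_k1_pct": budget.combined_standard_percent,
            "budget_combined_expanded_pct": budget.combined_percent,
            "budget_adopted_pct": budget.adopted_percent,
            "pct_diff_ranges": {k: list(v) for k, v in table.ranges().items()},
            "timings_s": timings,
        }
    )

    table.frame.to_csv(out_dir / "agreement_table.csv", index=False)
    (out_dir / "agreement_report.md").write_text(table.to_markdown())
    if config.write_volumes:
        write_volume(counts, out_dir / "spect_counts.nii.gz")
        write_volume(ct, out_dir / "ct.nii.gz")
        write_volume(act_fine, out_dir / "activity_quantified.nii.gz")
        write_volume(dose_ideal_abs.as_volume(), out_dir / "dose_ideal.nii.gz")
        write_volume(dose_image_abs.as_volume(), out_dir / "dose_image.nii.gz")
        spectra_rows = []
        for s in res_ideal.spectra:
            for c, v in zip(s.bin_centers_kev, s.values):
                spectra_rows.append(f"{s.scorer_id},{c},{v}")
        (out_dir / "fluence_spectra.csv").write_text(
            "scorer_id,energy_keV,fluence_per_cm2_per_history\n" + "\n".join(spectra_rows)
        )
    manifest["wall_time_s"] = time.time() - t0
    write_manifest(manifest, out_dir / "manifest.json")
    return PipelineResult(manifest, table, out_dir)


def make_fixtures(out_dir) -> dict[str, Path]:
    """Write all bundled data fixtures plus an example run configuration."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("i131_decay.csv", "tld_energy_response_synthetic.csv"):
        src = resources.files("rptdose.data").joinpath(name)
        dst = out / name
        dst.write_text(src.read_text())
        paths[name] = dst
    xs_path = out / "cross_sections.csv"
    build_table().to_csv(xs_path)
    paths["cross_sections.csv"] = xs_path
    cfg_path = out / "run.yaml"
    RunConfig(seed=17).to_yaml(cfg_path)
    paths["run.yaml"] = cfg_path
    return paths
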