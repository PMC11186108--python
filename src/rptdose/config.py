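"""Run configuration: one YAML document driving the whole pipeline.

Every physical quantity carries an explicit unit suffix in its key name
(``half_life_days``, ``a_admin_bq`` ...).  A seed is mandatory because the
SPECT noise, the Monte Carlo transport and the synthetic TLD readings are
all stochastic.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .grids import GridSpec
from .nuclide import AdministrationRecord, I131_HALF_LIFE_DAYS
from .phantom import PhantomConfig
from .spect import ScannerModel

__all__ = ["RunConfig", "TLDSettings", "TransportSettings", "CalibrationSettings"]

#: uncertainty-budget components (label, percent at k = 1) used by default:
#: TLD handling+calibration, energy-correction factors, energy interpolation,
#: setup/modeling — combined at k = 2 with a stated conservative 10% envelope
DEFAULT_BUDGET_COMPONENTS = (
    ("tld_handling_and_calibration", 4.4),
    ("energy_correction_factors", 0.6),
    ("energy_interpolation", 2.0),
    ("setup_and_modeling", 4.0),
)


@dataclass(frozen=True)
class TransportSettings:
    histories_image: int = 8_000_000
    histories_ideal: int = 12_000_000
    batches: int = 10
    cutoff_kev: float = 10.0
    voxelize_subsamples: int = 2


@dataclass(frozen=True)
class CalibrationSettings:
    cylinder_volume_l: float = 5.64
    uniform_conc_bq_ml: float = 1.0e5


@dataclass(frozen=True)
class TLDSettings:
    calibration_energy_kev: float = 111.0  # in-depth mean energy of the cal beam
    reference_energy_kev: float = 662.0  # Cs-137 anchor of the response curve
    repeatability_pct: float = 3.0  # expected chip-to-chip repeatability
    chips_per_probe: int = 4
    calibration_doses_gy: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)
    gain_signal_per_gy: float = 5.0  # synthetic reader gain
    budget_components: tuple[tuple[str, float], ...] = DEFAULT_BUDGET_COMPONENTS
    coverage_k: float = 2.0
    conservative_override_percent: float | None = 10.0
    response_curve_csv: str | None = None  # None -> bundled synthetic curve


@dataclass
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    scanner: ScannerModel = field(default_factory=ScannerModel)
    admin: AdministrationRecord = field(
        default_factory=lambda: AdministrationRecord(
            a_admin_bq=748e6, t_exposed_days=16.87, t_scan_days=7.1
        )
    )
    half_life_days: float = I131_HALF_LIFE_DAYS
    transport: TransportSettings = field(default_factory=TransportSettings)
    calibration: CalibrationSettings = field(default_factory=CalibrationSettings)
    tld: TLDSettings = field(default_factory=TLDSettings)
    seed: int = 0
    out_dir: str = "rptdose_run"
    write_volumes: bool = False

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory (stochastic stages are enabled)")
        if self.half_life_days <= 0:
            raise ValueError("half_life_days must be > 0")
        if self.tld.response_curve_csv and not Path(self.tld.response_curve_csv).exists():
            raise FileNotFoundError(self.tld.response_curve_csv)

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "phantom": asdict(self.phantom),
            "scanner": {
                "psf_fwhm_mm": self.scanner.psf_fwhm_mm,
                "sensitivity_cps_per_bq": self.scanner.sensitivity_cps_per_bq,
                "scan_duration_s": self.scanner.scan_duration_s,
                "noise": self.scanner.noise,
                "spect_grid": _grid_dict(self.scanner.spect_grid),
                "ct_grid": _grid_dict(self.scanner.ct_grid),
            },
            "administration": asdict(self.admin),
            "half_life_days": self.half_life_days,
            "transport": asdict(self.transport),
            "calibration": asdict(self.calibration),
            "tld": asdict(self.tld),
            "seed": self.seed,
            "out_dir": self.out_dir,
            "write_volumes": self.write_volumes,
        }
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        try:
            phantom = PhantomConfig(**_tupled(d.get("phantom", {}),
                                              ("probe_positions_mm", "materials", "sphere_center_mm")))
            sc = dict(d.get("scanner", {}))
            for key in ("spect_grid", "ct_grid"):
                if key in sc:
                    sc[key] = _grid_from_dict(sc[key])
            sc.setdefault("seed", d.get("seed", 0))
            scanner = ScannerModel(**sc)
            admin = AdministrationRecord(**d.get("administration", {}))
            cfg = cls(
                phantom=phantom,
                scanner=scanner,
                admin=admin,
                half_life_days=d.get("half_life_days", I131_HALF_LIFE_DAYS),
                transport=TransportSettings(**d.get("transport", {})),
                calibration=CalibrationSettings(**d.get("calibration", {})),
                tld=TLDSettings(**_tupled(d.get("tld", {}),
                                          ("budget_components", "calibration_doses_gy"))),
                seed=d["seed"],
                out_dir=d.get("out_dir", "rptdose_run"),
                write_volumes=d.get("write_volumes", False),
            )
        except (TypeError, KeyError) as exc:
            raise ValueError(f"invalid run configuration: {exc}") from exc
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _grid_dict(g: GridSpec) -> dict:
    return {"shape": list(g.shape), "spacing_mm": list(g.spacing), "origin_mm": list(g.origin)}


def _grid_from_dict(d: dict) -> GridSpec:
    return GridSpec(tuple(d["shape"]), tuple(d["spacing_mm"]), tuple(d["origin_mm"]))


def _tupled(d: dict, keys) -> dict:
    """YAML gives lists; restore the tuple-of-tuples fields dataclasses expect."""
    out = dict(d)
    for k in keys:
        if k in out and isinstance(out[k], list):
            out[k] = tuple(tuple(x) if isinstance(x, list) else x for x in out[k])
    return out
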