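"""TLD-style measured-dose reduction.

Raw light-output readings are converted to absorbed dose by a linear
calibration against NIST-traceable-style reference doses, then corrected
for the difference in beam quality between the calibration beam and the
photon spectrum at the probe, by interpolating the relative energy-response
curve linearly in log energy.  Group statistics flag readings deviating
more than 6% from the group mean (flagged readings stay in the mean), and
the uncertainty budget combines components in quadrature with a coverage
factor, optionally alongside a stated conservative value.

No fading correction is applied.  The bundled response curve is synthetic
(see ``data/tld_energy_response_synthetic.csv``) and overridable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "EnergyResponseCurve",
    "CalibrationFit",
    "TLDGroup",
    "UncertaintyBudget",
    "fit_calibration",
    "energy_correction",
    "flag_outliers",
    "combine_uncertainty",
    "reduce_probe",
    "apply_corrections",
    "load_default_response_curve",
]

OUTLIER_THRESHOLD_PCT = 6.0


@dataclass(frozen=True)
class EnergyResponseCurve:
    """Relative TLD response vs photon mean energy, w.r.t. a reference quality."""

    anchors: tuple[tuple[float, float], ...]  # (mean energy keV, relative response)
    reference_quality: str = "Cs-137"

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise ValueError("response curve needs at least two anchors")
        energies = [e for e, _ in self.anchors]
        if any(e <= 0 for e in energies) or any(r <= 0 for _, r in self.anchors):
            raise ValueError("anchor energies and responses must be > 0")
        if any(b <= a for a, b in zip(energies, energies[1:])):
            raise ValueError("anchor energies must be strictly increasing")

    def response(self, energy_kev: float) -> float:
        """Relative response, interpolated linearly in log energy."""
        if energy_kev <= 0:
            raise ValueError("energy must be > 0")
        e = np.array([a for a, _ in self.anchors])
        r = np.array([b for _, b in self.anchors])
        if not (e[0] <= energy_kev <= e[-1]):
            warnings.warn(
                f"energy {energy_kev:.1f} keV outside the response-curve span "
                f"[{e[0]:.0f}, {e[-1]:.0f}] keV; extrapolating",
                stacklevel=2,
            )
        return float(np.interp(math.log(energy_kev), np.log(e), r))


def load_default_response_curve(path=None) -> EnergyResponseCurve:
    if path is None:
        with resources.files("rptdose.data").joinpath(
            "tld_energy_response_synthetic.csv"
        ).open() as fh:
            df = pd.read_csv(fh, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    anchors = tuple(
        (float(r["energy_keV"]), float(r["relative_response"])) for _, r in df.iterrows()
    )
    return EnergyResponseCurve(anchors)


@dataclass(frozen=True)
class CalibrationFit:
    """Linear dose-response calibration: dose = slope * signal + intercept."""

    slope: float  # Gy per signal unit
    intercept: float  # Gy
    residual_sd_gy: float
    residual_sd_pct: float  # budget component: residual sd / mean dose


def fit_calibration(signals, reference_doses_gy) -> CalibrationFit:
    """Least-squares linear fit of dose against signal."""
    s = np.asarray(signals, dtype=np.float64)
    d = np.asarray(reference_doses_gy, dtype=np.float64)
    if s.size != d.size or s.size < 3:
        raise ValueError("need at least 3 (signal, dose) pairs")
    if np.ptp(s) == 0:
        raise ValueError("calibration signals are all equal (rank-deficient fit)")
    A = np.stack([s, np.ones_like(s)], axis=1)
    (slope, intercept), *_ = np.linalg.lstsq(A, d, rcond=None)
    resid = d - (slope * s + intercept)
    dof = max(s.size - 2, 1)
    sd = float(np.sqrt((resid**2).sum() / dof))
    mean_dose = float(d.mean())
    return CalibrationFit(float(slope), float(intercept), sd,
                          100.0 * sd / mean_dose if mean_dose else float("inf"))


def energy_correction(
    mean_energy_kev: float, curve: EnergyResponseCurve, calibration_energy_kev: float
) -> float:
    """Beam-quality correction factor applied to the calibrated dose:
    response(calibration beam) / response(measurement spectrum)."""
    if mean_energy_kev <= 0 or calibration_energy_kev <= 0:
        raise ValueError("energies must be > 0")
    return curve.response(calibration_energy_kev) / curve.response(mean_energy_kev)


@dataclass
class TLDGroup:
    """The chips of one probe: raw readings through corrected doses."""

    probe_id: int
    readings: np.ndarray  # raw signals, arbitrary (nC-like) units
    calibration: CalibrationFit
    mean_energy_at_probe_kev: float
    corrected_doses_gy: np.ndarray | None = None
    outlier_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.readings = np.asarray(self.readings, dtype=np.float64)
        if np.any(self.readings <= 0):
            raise ValueError("raw readings must be > 0")


def apply_corrections(
    group: TLDGroup, curve: EnergyResponseCurve, calibration_energy_kev: float
) -> TLDGroup:
    """Populate corrected doses: (slope * signal + intercept) * energy factor."""
    f = energy_correction(group.mean_energy_at_probe_kev, curve, calibration_energy_kev)
    cal = group.calibration
    group.corrected_doses_gy = (cal.slope * group.readings + cal.intercept) * f
    group.outlier_flags = flag_outliers(group.corrected_doses_gy)
    return group


def flag_outliers(values, threshold_pct: float = OUTLIER_THRESHOLD_PCT) -> np.ndarray:
    """Flag readings deviating more than ``threshold_pct`` of the group mean.

    Flagged readings are *retained* in all statistics; the flags are
    reporting metadata only.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 readings for outlier statistics")
    mean = x.mean()
    if mean == 0:
        raise ValueError("group mean is zero")
    return np.abs(x - mean) / abs(mean) * 100.0 > threshold_pct


@dataclass
class UncertaintyBudget:
    """Quadrature uncertainty budget with coverage factor ``k``.

    ``combined_percent`` is the computed expanded uncertainty
    k * sqrt(sum c_i^2); when a conservative override is stated,
    ``adopted_percent`` carries it and both values are reported.
    """

    components: tuple[tuple[str, float], ...]  # (label, percent at k=1)
    k: float = 2.0
    conservative_override_percent: float | None = None

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("coverage factor must be > 0")
        if any(c < 0 for _, c in self.components):
            raise ValueError("budget components must be >= 0")

    @property
    def combined_standard_percent(self) -> float:
        """k = 1 quadrature sum."""
        return math.sqrt(sum(c**2 for _, c in self.components))

    @property
    def combined_percent(self) -> float:
        return self.k * self.combined_standard_percent

    @property
    def adopted_percent(self) -> float:
        if self.conservative_override_percent is not None:
            return self.conservative_override_percent
        return self.combined_percent


def combine_uncertainty(
    components, k: float = 2.0, conservative_override_percent: float | None = None
) -> UncertaintyBudget:
    """Build an :class:`UncertaintyBudget` from (label, percent) pairs."""
    comps = tuple((str(label), float(c)) for label, c in components)
    return UncertaintyBudget(comps, k, conservative_override_percent)


def reduce_probe(group: TLDGroup) -> tuple[float, float]:
    """Measured dose of one probe: mean of corrected doses, sd as % of mean."""
    if group.corrected_doses_gy is None:
        raise ValueError("corrected doses not populated; run apply_corrections first")
    d = np.asarray(group.corrected_doses_gy, dtype=np.float64)
    mean = float(d.mean())
    if d.size < 2:
        warnings.warn("fewer than 2 readings; standard deviation unavailable", stacklevel=2)
        return mean, float("nan")
    sd_pct = 100.0 * float(d.std(ddof=1)) / mean if mean else float("inf")
    return mean, sd_pct
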