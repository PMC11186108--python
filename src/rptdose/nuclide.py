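"""Radionuclide decay bookkeeping: decay constant, activity decay, cumulated
(time-integrated) activity and per-history dose scaling.

Activities are carried in Bq and times in days at every interface; the
day -> second conversion happens exactly once, inside
:func:`integrated_activity`.  The cumulated activity of a source with
initial activity ``A_admin`` observed for ``t_exposed`` days is

    A_tilde = (A_admin / lambda) * (1 - exp(-lambda * t_exposed))   [Bq s]

and the absorbed dose follows as ``D = A_tilde * D_history`` where
``D_history`` is the Monte Carlo dose per decay (Gy/history).

Emission data (photon lines and the per-decay mean beta energy) for I-131
ship as a CSV compiled from published decay-data evaluations and can be
overridden by the run configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "NuclideData",
    "AdministrationRecord",
    "CumulatedActivity",
    "decay_constant",
    "activity_at",
    "integrated_activity",
    "absolute_dose",
    "load_i131",
]

SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class NuclideData:
    """Half-life, photon emission lines and mean beta energy per decay."""

    name: str
    half_life_days: float
    photon_lines: tuple[tuple[float, float], ...]  # (energy keV, yield/decay)
    beta_mean_energy_kev: float

    def __post_init__(self) -> None:
        if self.half_life_days <= 0:
            raise ValueError("half-life must be > 0")
        for e, y in self.photon_lines:
            if e <= 0 or y < 0:
                raise ValueError("photon lines need energy > 0 and yield >= 0")
        if self.beta_mean_energy_kev < 0:
            raise ValueError("beta mean energy must be >= 0")

    @property
    def decay_constant_per_day(self) -> float:
        return decay_constant(self.half_life_days)

    @property
    def total_photon_yield(self) -> float:
        return sum(y for _, y in self.photon_lines)


@dataclass(frozen=True)
class AdministrationRecord:
    """Administered activity and the timing of scan and TLD exposure.

    ``t_exposed_days`` is the residence time of the dosimeters counted from
    the reference time of ``a_admin_bq``; ``t_scan_days`` is the imaging
    time post administration.
    """

    a_admin_bq: float
    t_exposed_days: float
    t_scan_days: float = 0.0

    def __post_init__(self) -> None:
        if self.a_admin_bq < 0:
            raise ValueError("administered activity must be >= 0")
        if self.t_exposed_days < 0 or self.t_scan_days < 0:
            raise ValueError("times must be >= 0")


@dataclass(frozen=True)
class CumulatedActivity:
    """Time-integrated activity A_tilde in Bq s."""

    a_tilde_bq_s: float

    def __post_init__(self) -> None:
        if self.a_tilde_bq_s < 0:
            raise ValueError("cumulated activity must be >= 0")


def decay_constant(half_life_days: float) -> float:
    """lambda = ln 2 / T_1/2, in 1/day."""
    if half_life_days <= 0:
        raise ValueError(f"half-life must be > 0, got {half_life_days}")
    return math.log(2.0) / half_life_days


def activity_at(record: AdministrationRecord, lam_per_day: float, t_days: float) -> float:
    """Activity A(t) = A_admin * exp(-lambda t), Bq."""
    if t_days < 0:
        raise ValueError("t must be >= 0")
    return record.a_admin_bq * math.exp(-lam_per_day * t_days)


def integrated_activity(
    record: AdministrationRecord, lam_per_day: float
) -> CumulatedActivity:
    """Cumulated activity over the exposure window, Bq s."""
    if lam_per_day <= 0:
        raise ValueError("decay constant must be > 0")
    if record.t_exposed_days < 0:
        raise ValueError("exposure time must be >= 0")
    lam_per_s = lam_per_day / SECONDS_PER_DAY
    a_tilde = record.a_admin_bq / lam_per_s * (-math.expm1(-lam_per_day * record.t_exposed_days))
    return CumulatedActivity(a_tilde)


def absolute_dose(dose_per_history_gy: float, a_tilde: CumulatedActivity | float) -> float:
    """Scale a per-decay Monte Carlo dose to absolute Gy: D = A_tilde * D_history."""
    at = a_tilde.a_tilde_bq_s if isinstance(a_tilde, CumulatedActivity) else float(a_tilde)
    if dose_per_history_gy < 0 or at < 0:
        raise ValueError("dose per history and cumulated activity must be >= 0")
    return at * dose_per_history_gy


#: I-131 half-life in days
I131_HALF_LIFE_DAYS = 8.0197


def load_i131(csv_path=None) -> NuclideData:
    """I-131 emission data from the bundled (or an overriding) CSV."""
    if csv_path is None:
        with resources.files("rptdose.data").joinpath("i131_decay.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(csv_path)
    photons = df[df["particle"] == "gamma"]
    beta = df[df["particle"] == "beta_mean"]
    lines = tuple(
        (float(r["energy_keV"]), float(r["yield_per_decay"])) for _, r in photons.iterrows()
    )
    beta_e = float((beta["energy_keV"] * beta["yield_per_decay"]).sum())
    return NuclideData("I-131", I131_HALF_LIFE_DAYS, lines, beta_e)
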