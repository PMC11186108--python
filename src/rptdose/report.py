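"""Agreement table: measured vs image-mode vs idealized-mode probe doses.

Percent differences use the measured (TLD) dose as the reference,
100 * (measured - comparator) / measured, so a comparator *above* the
measurement gives a negative difference.  The verdict per probe checks the
difference against the expanded measurement-uncertainty budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tld import UncertaintyBudget
from .transport import DoseGrid, ScorerSpec

__all__ = ["ProbeComparison", "AgreementTable", "roi_mean_dose", "percent_difference", "agreement_report"]


def roi_mean_dose(
    dose: DoseGrid, roi: ScorerSpec, subsamples: int = 4
) -> tuple[float, float]:
    """Volume-weighted mean dose over a cubic ROI, with propagated MC
    uncertainty (per-voxel uncertainties assumed independent).

    Fractional voxel overlap is evaluated by sampling ``subsamples**3``
    points uniformly in the ROI.
    """
    grid = dose.grid
    offs = (np.arange(subsamples) + 0.5) / subsamples - 0.5
    c = np.asarray(roi.center_mm)
    pts = np.stack(
        np.meshgrid(*[c[a] + offs * roi.edge_mm for a in range(3)], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    idx = np.floor(
        (pts - np.asarray(grid.origin)) / np.asarray(grid.spacing) + 0.5
    ).astype(np.int64)
    inside = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
    if not inside.any():
        raise ValueError("ROI does not overlap the dose grid")
    idx = idx[inside]
    flat = idx @ np.array([grid.shape[1] * grid.shape[2], grid.shape[2], 1])
    uniq, counts = np.unique(flat, return_counts=True)
    w = counts / counts.sum()
    d = dose.dose.ravel()[uniq]
    s = d * dose.rel_uncertainty.ravel()[uniq]
    mean = float((w * d).sum())
    sigma = float(np.sqrt(((w * s) ** 2).sum()))
    rel = sigma / mean if mean > 0 else 0.0
    return mean, rel


def percent_difference(measured_gy: float, comparator_gy: float) -> float:
    """100 * (measured - comparator) / measured."""
    if measured_gy == 0:
        raise ValueError("measured dose is zero; percent difference undefined")
    return 100.0 * (measured_gy - comparator_gy) / measured_gy


@dataclass
class ProbeComparison:
    probe_id: int
    measured_gy: float | None = None
    measured_sd_pct: float | None = None
    image_gy: float | None = None
    image_rel_unc: float | None = None
    ideal_gy: float | None = None
    ideal_rel_unc: float | None = None

    @property
    def complete(self) -> bool:
        return None not in (self.measured_gy, self.image_gy, self.ideal_gy)


@dataclass
class AgreementTable:
    frame: pd.DataFrame
    budget: UncertaintyBudget
    incomplete_probes: list[int]

    def ranges(self) -> dict[str, tuple[float, float]]:
        out = {}
        for col in ("pct_diff_measured_image", "pct_diff_measured_ideal"):
            vals = self.frame[col].dropna()
            if len(vals):
                out[col] = (float(vals.min()), float(vals.max()))
        return out

    def to_markdown(self) -> str:
        lines = [
            "# Probe dose agreement",
            "",
            f"Expanded uncertainty envelope: {self.budget.adopted_percent:.1f}% "
            f"(computed k={self.budget.k:g} quadrature: {self.budget.combined_percent:.1f}%)",
            "",
            self.frame.to_markdown(index=False, floatfmt=".2f"),
            "",
        ]
        for col, (lo, hi) in self.ranges().items():
            lines.append(f"- {col}: {lo:+.2f}% to {hi:+.2f}%")
        if self.incomplete_probes:
            lines.append(f"- incomplete probes (missing a mode): {self.incomplete_probes}")
        return "\n".join(lines)


def agreement_report(
    rows: list[ProbeComparison], budget: UncertaintyBudget
) -> AgreementTable:
    """Assemble the per-probe agreement table with uncertainty verdicts."""
    records = []
    incomplete = []
    envelope = budget.adopted_percent
    for r in sorted(rows, key=lambda x: x.probe_id):
        if not r.complete:
            incomplete.append(r.probe_id)
        pd_image = (
            percent_difference(r.measured_gy, r.image_gy)
            if r.measured_gy and r.image_gy is not None
            else np.nan
        )
        pd_ideal = (
            percent_difference(r.measured_gy, r.ideal_gy)
            if r.measured_gy and r.ideal_gy is not None
            else np.nan
        )
        records.append(
            {
                "probe": r.probe_id,
                "measured_gy": r.measured_gy,
                "measured_sd_pct": r.measured_sd_pct,
                "image_gy": r.image_gy,
                "image_mc_rel_unc_pct": 100 * r.image_rel_unc
                if r.image_rel_unc is not None
                else np.nan,
                "ideal_gy": r.ideal_gy,
                "ideal_mc_rel_unc_pct": 100 * r.ideal_rel_unc
                if r.ideal_rel_unc is not None
                else np.nan,
                "pct_diff_measured_image": pd_image,
                "pct_diff_measured_ideal": pd_ideal,
                "within_uncertainty": bool(abs(pd_image) <= envelope)
                if np.isfinite(pd_image)
                else False,
            }
        )
    frame = pd.DataFrame.from_records(records)
    return AgreementTable(frame, budget, incomplete)
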