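"""Carbonate screening of respired CO₂ and incubation-derived decomposability.

In carbonate-bearing soils part of the CO₂ evolved during incubation can
come from carbonate weathering rather than microbial SOC decomposition.
Because geogenic carbonate is ¹⁴C-free (−1000 ‰) and isotopically heavy in
δ¹³C (≈0 ‰ vs. ≈−27 ‰ for plant-derived C), a two-endmember δ¹³C mixing
model estimates the carbonate fraction f of the respired CO₂, and Δ¹⁴CO₂
is either corrected (f ≤ 5%) or the layer's respired-CO₂ constraint is
excluded from modelling (f > 5%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CARBONATE_EXCLUSION_THRESHOLD",
    "CarbonateAssessment",
    "IncubationSeries",
    "estimate_carbonate_fraction",
    "correct_d14c_co2",
    "decomposability",
    "screen_observations",
]

#: carbonate fraction above which the respired-CO2 constraint is discarded
CARBONATE_EXCLUSION_THRESHOLD = 0.05

#: default isotopic signature of geogenic carbonate
D13C_CARBONATE_DEFAULT = 0.0
D14C_CARBONATE_DEFAULT = -1000.0


@dataclass(frozen=True)
class CarbonateAssessment:
    f_carbonate: float
    corrected_d14c_co2: float  # NaN when excluded
    excluded: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_carbonate <= 1.0:
            raise ValueError("f_carbonate outside [0, 1]")
        if not self.excluded and self.corrected_d14c_co2 < -1000.0:
            raise ValueError("corrected Delta14C below -1000 permil")


@dataclass(frozen=True)
class IncubationSeries:
    """Cumulative CO₂-C release from one jar incubation."""

    timepoints_h: np.ndarray
    cumulative_co2c_ug: np.ndarray
    soc_mass_g: float

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints_h, dtype=float)
        c = np.asarray(self.cumulative_co2c_ug, dtype=float)
        object.__setattr__(self, "timepoints_h", t)
        object.__setattr__(self, "cumulative_co2c_ug", c)
        if t.size < 2:
            raise ValueError("need at least two incubation timepoints")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(np.diff(c) < 0):
            raise ValueError("cumulative CO2-C must be non-decreasing")
        if self.soc_mass_g <= 0:
            raise ValueError("soc_mass_g must be positive")


def estimate_carbonate_fraction(
    d13c_measured: float,
    d13c_biogenic: float,
    d13c_carbonate: float = D13C_CARBONATE_DEFAULT,
) -> float:
    """Carbonate fraction of respired CO₂ from two-endmember δ¹³C mixing.

    f = (δ_meas − δ_bio)/(δ_carb − δ_bio), clipped to [0, 1]. The biogenic
    endmember is taken from the bulk-SOC δ¹³C of the same layer.
    """
    if d13c_biogenic == d13c_carbonate:
        raise ValueError("degenerate mixing: endmembers coincide")
    f = (d13c_measured - d13c_biogenic) / (d13c_carbonate - d13c_biogenic)
    return float(np.clip(f, 0.0, 1.0))


def correct_d14c_co2(
    d14c_measured: float,
    f: float,
    d14c_carbonate: float = D14C_CARBONATE_DEFAULT,
) -> CarbonateAssessment:
    """Remove the carbonate contribution from a measured Δ¹⁴CO₂ value.

    The biogenic signature is recovered by unmixing,
    Δ_bio = (Δ_meas − f·Δ_carb)/(1 − f), for f at or below the 5%
    threshold; above it the layer is excluded and no corrected value is
    reported.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("carbonate fraction outside [0, 1]")
    if f > CARBONATE_EXCLUSION_THRESHOLD or f >= 1.0:
        return CarbonateAssessment(
            f_carbonate=f, corrected_d14c_co2=float("nan"), excluded=True
        )
    corrected = (d14c_measured - f * d14c_carbonate) / (1.0 - f)
    return CarbonateAssessment(
        f_carbonate=f, corrected_d14c_co2=corrected, excluded=False
    )


def decomposability(series: IncubationSeries) -> float:
    """Mean respiration rate per unit SOC, µg CO₂-C (g SOC)⁻¹ h⁻¹.

    Total CO₂-C released over the incubation divided by the SOC mass in
    the jar and the elapsed time — the time-integrated respiration rate
    normalised to SOC content.
    """
    t = series.timepoints_h
    c = series.cumulative_co2c_ug
    elapsed = t[-1] - t[0]
    if elapsed <= 0:
        raise ValueError("zero elapsed incubation time")
    return float((c[-1] - c[0]) / series.soc_mass_g / elapsed)


def screen_observations(
    obs: pd.DataFrame,
    d13c_carbonate: float = D13C_CARBONATE_DEFAULT,
    d14c_carbonate: float = D14C_CARBONATE_DEFAULT,
) -> pd.DataFrame:
    """Apply carbonate screening to an observation table.

    Expects columns ``d13c_co2_permil``, ``d13c_soc_permil`` and
    ``d14c_co2_permil``; returns a copy with ``f_carbonate``,
    ``corrected_d14c_co2_permil``, ``excluded`` and ``reason`` columns.
    Rows without δ¹³C data pass through unscreened (f = 0).
    """
    out = obs.copy()
    fs, corrected, excl, reasons = [], [], [], []
    for _, row in obs.iterrows():
        d13c_meas = row.get("d13c_co2_permil", np.nan)
        d13c_bio = row.get("d13c_soc_permil", np.nan)
        if np.isnan(d13c_meas) or np.isnan(d13c_bio):
            fs.append(0.0)
            corrected.append(row["d14c_co2_permil"])
            excl.append(False)
            reasons.append("")
            continue
        f = estimate_carbonate_fraction(d13c_meas, d13c_bio, d13c_carbonate)
        assessment = correct_d14c_co2(row["d14c_co2_permil"], f, d14c_carbonate)
        fs.append(f)
        corrected.append(assessment.corrected_d14c_co2)
        excl.append(assessment.excluded)
        reasons.append("carbonate_fraction_gt_5pct" if assessment.excluded else "")
    out["f_carbonate"] = fs
    out["corrected_d14c_co2_permil"] = corrected
    out["excluded"] = excl
    out["reason"] = reasons
    return out
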