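"""Radiocarbon conventions and the atmospheric Δ¹⁴C forcing record.

All ¹⁴C quantities follow the Δ¹⁴C reporting convention: a sample's
decay-corrected ¹⁴C/¹²C ratio expressed as a per-mil deviation from the
1950 atmospheric standard,

    Δ¹⁴C = (F · exp(λ (1950 − y)) − 1) · 1000,

where ``F`` is the absolute fraction modern, ``y`` the collection year and
``λ = 1/8267 yr⁻¹`` the radiocarbon decay constant. −1000 ‰ is the
radiocarbon-free endmember (F = 0).

The time-varying atmospheric signature — the pre-industrial plateau, the
early-1960s bomb spike and its subsequent relaxation — is carried by
:class:`AtmosphericRecord`, interpolated to a yearly grid at load time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "LAMBDA_14C",
    "REFERENCE_YEAR",
    "RadiocarbonConstants",
    "RadiocarbonValue",
    "AtmosphericRecord",
    "fm_from_delta",
    "delta_from_fm",
    "equilibrium_fm",
    "load_atmospheric_record",
]

#: Radiocarbon decay constant, 1/8267 per year.
LAMBDA_14C: float = 1.0 / 8267.0

#: Calendar year of the radiocarbon reporting standard.
REFERENCE_YEAR: int = 1950


@dataclass(frozen=True)
class RadiocarbonConstants:
    """Physical constants of the ¹⁴C system (immutable)."""

    lambda_decay: float = LAMBDA_14C
    reference_year: int = REFERENCE_YEAR

    def __post_init__(self) -> None:
        if self.lambda_decay <= 0:
            raise ValueError("lambda_decay must be positive")


@dataclass(frozen=True)
class RadiocarbonValue:
    """A single Δ¹⁴C measurement tied to its collection year."""

    delta14c: float
    collection_year: float
    fraction_modern: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "fraction_modern",
            fm_from_delta(self.delta14c, self.collection_year),
        )


def fm_from_delta(delta14c: float, collection_year: float) -> float:
    """Absolute fraction modern from Δ¹⁴C (‰) and collection year.

    Inverts Δ¹⁴C = (F·e^{λ(1950−y)} − 1)·1000, so F = (Δ/1000 + 1)·e^{λ(y−1950)}.

    Raises
    ------
    ValueError
        If ``delta14c`` < −1000 ‰ (below the ¹⁴C-free endmember).
    """
    if delta14c < -1000.0:
        raise ValueError(f"delta14c below -1000 permil: {delta14c}")
    return (delta14c / 1000.0 + 1.0) * math.exp(
        LAMBDA_14C * (collection_year - REFERENCE_YEAR)
    )


def delta_from_fm(fraction_modern: float, collection_year: float) -> float:
    """Δ¹⁴C (‰) from absolute fraction modern and collection year."""
    if fraction_modern < 0:
        raise ValueError(f"fraction_modern must be >= 0, got {fraction_modern}")
    return (
        fraction_modern * math.exp(LAMBDA_14C * (REFERENCE_YEAR - collection_year))
        - 1.0
    ) * 1000.0


def equilibrium_fm(k: float, fm_atm: float) -> float:
    """Pre-bomb spin-up fraction modern of a single pool.

    For a pool turning over at rate ``k`` under a constant atmosphere with
    fraction modern ``fm_atm``, the steady state of
    dF/dt = k(F_atm − F) − λF is ``fm_atm · k/(k + λ)``: fast pools track
    the atmosphere, slow pools are depleted by decay during storage.
    """
    if k <= 0:
        raise ValueError(f"decomposition rate k must be positive, got {k}")
    if fm_atm < 0:
        raise ValueError(f"fm_atm must be >= 0, got {fm_atm}")
    return fm_atm * k / (k + LAMBDA_14C)


@dataclass(frozen=True)
class AtmosphericRecord:
    """Yearly atmospheric Δ¹⁴C series — the model's input signature I₁₄C(t).

    ``years`` is a gap-free, strictly increasing integer grid; irregular
    source records are linearly interpolated at load time. Before
    ``years[0]`` the atmosphere is treated as constant at ``delta14c[0]``
    (the pre-bomb plateau), which makes the analytic spin-up exact.
    """

    years: np.ndarray
    delta14c: np.ndarray
    zone_label: str = ""

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=float)
        d14c = np.asarray(self.delta14c, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "delta14c", d14c)
        if years.ndim != 1 or years.size < 2:
            raise ValueError("record needs at least two yearly values")
        if d14c.shape != years.shape:
            raise ValueError("years and delta14c must have equal length")
        diffs = np.diff(years)
        if not np.allclose(diffs, 1.0):
            raise ValueError("years must form a gap-free yearly grid")
        if np.any(d14c < -1000.0):
            raise ValueError("atmospheric Delta14C below -1000 permil")
        object.__setattr__(self, "_fm_cache", {})

    @property
    def start_year(self) -> float:
        return float(self.years[0])

    @property
    def end_year(self) -> float:
        return float(self.years[-1])

    def delta_at(self, year: float) -> float:
        """Δ¹⁴C at ``year``; constant extension before the record start."""
        if year <= self.start_year:
            return float(self.delta14c[0])
        if year > self.end_year:
            raise ValueError(
                f"year {year} beyond record end {self.end_year}"
            )
        return float(np.interp(year, self.years, self.delta14c))

    def fm_series(self, first_year: float, last_year: float) -> np.ndarray:
        """Fraction-modern values on the integer years [first, last].

        Constant extension before the record start; cached per year range
        (the fitting loop re-requests the same span thousands of times).
        """
        key = (float(first_year), float(last_year))
        cached = self._fm_cache.get(key)  # type: ignore[attr-defined]
        if cached is not None:
            return cached
        if last_year > self.end_year:
            raise ValueError(f"year {last_year} beyond record end {self.end_year}")
        yrs = np.arange(first_year, last_year + 1)
        # np.interp clamps on the left, giving the constant pre-record plateau
        deltas = np.interp(yrs, self.years, self.delta14c)
        fm = (deltas / 1000.0 + 1.0) * np.exp(LAMBDA_14C * (yrs - REFERENCE_YEAR))
        fm.setflags(write=False)
        self._fm_cache[key] = fm  # type: ignore[attr-defined]
        return fm

    def shifted(self, lag_years: int = 0, offset: float = 0.0) -> "AtmosphericRecord":
        """Apply an input time lag and a constant ‰ offset.

        A lag of ``n`` years means carbon entering the soil in year ``y``
        carries the atmospheric signature of year ``y − n`` (litter and
        root turnover delay); the series is shifted ``n`` years later.
        """
        return AtmosphericRecord(
            years=self.years + lag_years,
            delta14c=self.delta14c + offset,
            zone_label=self.zone_label,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.years.astype(int), "delta14c_permil": self.delta14c}
        )


def load_atmospheric_record(
    path: Union[str, Path],
    lag_years: int = 0,
    offset: float = 0.0,
    zone_label: str = "",
) -> AtmosphericRecord:
    """Read an atmospheric Δ¹⁴C CSV and regrid it to yearly resolution.

    The file must have columns ``year`` and ``delta14c_permil`` (``#``
    comments allowed); years may be irregular and are linearly
    interpolated onto the integer-year grid spanning the record. ``lag_years``
    and ``offset`` are the per-site bomb-curve adjustment knobs (default
    off), applied after regridding.
    """
    df = pd.read_csv(path, comment="#")
    missing = {"year", "delta14c_permil"} - set(df.columns)
    if missing:
        raise ValueError(f"atmospheric CSV missing columns: {sorted(missing)}")
    years = df["year"].to_numpy(dtype=float)
    d14c = df["delta14c_permil"].to_numpy(dtype=float)
    if years.size < 2:
        raise ValueError("atmospheric CSV needs at least two rows")
    if np.any(np.diff(years) <= 0):
        raise ValueError("atmospheric CSV years must be strictly increasing")
    if np.any(d14c < -1000.0):
        raise ValueError("atmospheric CSV contains Delta14C < -1000 permil")
    grid = np.arange(math.ceil(years[0]), math.floor(years[-1]) + 1, dtype=float)
    interp = np.interp(grid, years, d14c)
    record = AtmosphericRecord(years=grid, delta14c=interp, zone_label=zone_label)
    if lag_years or offset:
        record = record.shifted(lag_years=lag_years, offset=offset)
    return record
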