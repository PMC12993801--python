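"""Self-contained synthetic study generator.

Emulates the field-campaign structure the pipeline was built for — a
network of sites across five land uses (temperate and alpine grasslands,
forests, croplands and managed peatlands), each sampled over fixed depth
increments (0–5, 5–10, 10–20, 20–40 and 40–90 cm, plus an organic layer
in forests) — with a parametric bomb curve, known two-pool parameters per
layer, depth-covarying soil properties, and Gaussian measurement noise at
the measurement uncertainties of gas-source (σ ≈ 2 ‰) and bulk-SOC
(σ ≈ 7 ‰) AMS. Everything is exactly regenerable from (config, seed).

What it deliberately does not emulate: spatial autocorrelation among
sites, seasonal input variability, non-steady-state land-use history, and
incubation gas-exchange physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .radiocarbon import AtmosphericRecord
from .twopool import (
    TwoPoolSeriesParams,
    forward_delta14c,
    system_age_distribution,
    transit_time_distribution,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "synth_atmosphere",
    "synth_sites",
    "synth_observations",
    "OBSERVATION_COLUMNS",
]

MINERAL_BINS: Tuple[Tuple[float, float], ...] = (
    (0.0, 5.0),
    (5.0, 10.0),
    (10.0, 20.0),
    (20.0, 40.0),
    (40.0, 90.0),
)

# per-land-use topsoil parameter ranges (log-uniform draws); values chosen
# to span litter-like to millennial turnover within the calibration prior
_LANDUSE_RANGES: Dict[str, Dict[str, Tuple[float, float]]] = {
    "temperate_grassland": {"k_fast": (0.1, 1.0), "k_slow": (3e-3, 3e-2), "alpha": (0.1, 0.3)},
    "alpine_grassland": {"k_fast": (0.05, 0.5), "k_slow": (1e-3, 1e-2), "alpha": (0.1, 0.3)},
    "forest": {"k_fast": (0.1, 2.0), "k_slow": (2e-3, 2e-2), "alpha": (0.05, 0.2)},
    "cropland": {"k_fast": (0.1, 1.0), "k_slow": (5e-3, 5e-2), "alpha": (0.1, 0.3)},
    "managed_peatland": {"k_fast": (0.02, 0.2), "k_slow": (1e-4, 4e-4), "alpha": (0.2, 0.5)},
}

# turnover slows with depth: multiplicative factor on both rate ranges per bin
_DEPTH_RATE_FACTOR = (1.0, 0.6, 0.35, 0.2, 0.1)

OBSERVATION_COLUMNS = [
    "site",
    "land_use",
    "depth_top_cm",
    "depth_bottom_cm",
    "organic_layer",
    "obs_year",
    "d14c_co2_permil",
    "sd_co2_permil",
    "d14c_soc_permil",
    "sd_soc_permil",
    "d13c_co2_permil",
    "d13c_soc_permil",
    "soc_stock_kg_m2",
    "decomposability_ugC_gSOC_h",
    "roc_pct",
    "lag_years",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design knobs; defaults are the generator's study conditions."""

    n_sites: Dict[str, int] = field(
        default_factory=lambda: {
            "temperate_grassland": 4,
            "alpine_grassland": 4,
            "forest": 5,
            "cropland": 3,
            "managed_peatland": 3,
        }
    )
    seed: int = 20230101
    sd_co2_permil: float = 2.0
    sd_soc_permil: float = 7.0
    # bomb-curve shape
    curve_start_year: int = 1900
    curve_end_year: int = 2030
    baseline_permil: float = -5.0
    bomb_rise_start: int = 1955
    peak_year: int = 1964
    peak_permil: float = 700.0
    relaxation_tau_yr: float = 16.0
    late_slope_permil_yr: float = 0.0
    # observation years: alpine sites were sampled a year earlier
    obs_year_default: int = 2023
    obs_year_by_landuse: Dict[str, int] = field(
        default_factory=lambda: {"alpine_grassland": 2022}
    )
    forest_organic_layer: bool = True
    # carbonate injection: fractions applied to the first rows of the table
    carbonate_fractions: Tuple[float, ...] = ()
    d13c_carbonate: float = 0.0

    def obs_year(self, land_use: str) -> int:
        return self.obs_year_by_landuse.get(land_use, self.obs_year_default)


@dataclass(frozen=True)
class SyntheticTruth:
    """True parameters, derived ages, and covariates per site × layer."""

    table: pd.DataFrame
    config: SyntheticConfig
    seed: int


def synth_atmosphere(
    config: SyntheticConfig = SyntheticConfig(), seed: Optional[int] = None
) -> AtmosphericRecord:
    """Parametric atmospheric Δ¹⁴C curve with a bomb spike.

    Constant pre-bomb baseline, linear rise from ``bomb_rise_start`` to
    the configured peak, then exponential relaxation back toward the
    (optionally slowly drifting) baseline:

        Δ(y) = L(y) + (peak − L(peak_year)) · exp(−(y − peak_year)/τ),

    with L(y) = baseline + late_slope·(y − peak_year). Deterministic given
    the config; ``seed`` is accepted for interface symmetry but unused.
    """
    if config.peak_permil < -1000.0 or config.baseline_permil < -1000.0:
        raise ValueError("non-physical curve configuration (< -1000 permil)")
    if not (config.curve_start_year < config.peak_year < config.curve_end_year):
        raise ValueError("peak year must lie inside the record span")
    years = np.arange(config.curve_start_year, config.curve_end_year + 1, dtype=float)
    d14c = np.full_like(years, config.baseline_permil)
    rise = (years >= config.bomb_rise_start) & (years <= config.peak_year)
    span = max(config.peak_year - config.bomb_rise_start, 1)
    d14c[rise] = config.baseline_permil + (
        config.peak_permil - config.baseline_permil
    ) * (years[rise] - config.bomb_rise_start) / span
    post = years > config.peak_year
    late = config.baseline_permil + config.late_slope_permil_yr * (
        years[post] - config.peak_year
    )
    late_at_peak = config.baseline_permil
    d14c[post] = late + (config.peak_permil - late_at_peak) * np.exp(
        -(years[post] - config.peak_year) / config.relaxation_tau_yr
    )
    return AtmosphericRecord(years=years, delta14c=d14c, zone_label="synthetic")


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def synth_sites(
    config: SyntheticConfig = SyntheticConfig(), seed: Optional[int] = None
) -> SyntheticTruth:
    """Draw true (k_f, k_s, α) and covariates for every site × depth layer.

    Rates are drawn log-uniformly within per-land-use topsoil ranges and
    slowed with depth (factor 1 → 0.1 from 0–5 cm to 40–90 cm); k_s ≤ k_f
    is enforced. Covariates follow monotone depth trends: SOC stock and
    decomposability decline with depth, %-ROC increases with depth except
    in managed peatlands where it stays uniformly low.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if not config.n_sites or any(n <= 0 for n in config.n_sites.values()):
        raise ValueError("each land-use stratum needs at least one site")
    rows = []
    site_idx = 0
    for land_use, n in config.n_sites.items():
        if land_use not in _LANDUSE_RANGES:
            raise ValueError(f"no parameter ranges for land use {land_use!r}")
        ranges = _LANDUSE_RANGES[land_use]
        for _ in range(n):
            site_idx += 1
            site = f"S{site_idx:02d}_{land_use[:4]}"
            layers: list[Tuple[float, float, bool]] = []
            if land_use == "forest" and config.forest_organic_layer:
                layers.append((-5.0, 0.0, True))
            layers.extend((t, b, False) for t, b in MINERAL_BINS)
            for li, (top, bottom, organic) in enumerate(layers):
                depth_i = 0 if organic else (li - (1 if layers[0][2] else 0))
                fac = 1.5 if organic else _DEPTH_RATE_FACTOR[depth_i]
                kf = _loguniform(rng, *ranges["k_fast"]) * fac
                ks = _loguniform(rng, *ranges["k_slow"]) * fac
                ks = min(ks, kf)
                alpha = rng.uniform(*ranges["alpha"])
                p = TwoPoolSeriesParams(kf, ks, alpha)
                tt = transit_time_distribution(p)
                sa = system_age_distribution(p)
                # depth-covarying soil properties with mild lognormal scatter
                scatter = lambda s: float(np.exp(rng.normal(0.0, s)))
                soc_stock = 3.5 * math.exp(-0.6 * depth_i) * scatter(0.25)
                decomp = 8.0 * math.exp(-0.7 * depth_i) * scatter(0.3)
                if land_use == "managed_peatland":
                    roc = float(np.clip(rng.normal(6.0, 1.5), 1.0, 100.0))
                else:
                    roc = float(
                        np.clip(10.0 + 6.0 * depth_i + rng.normal(0.0, 2.0), 1.0, 100.0)
                    )
                rows.append(
                    {
                        "site": site,
                        "land_use": land_use,
                        "depth_top_cm": top,
                        "depth_bottom_cm": bottom,
                        "organic_layer": organic,
                        "obs_year": config.obs_year(land_use),
                        "k_fast": kf,
                        "k_slow": ks,
                        "alpha": alpha,
                        "tt_median_yr": tt.median,
                        "tt_mean_yr": tt.mean,
                        "sa_median_yr": sa.median,
                        "sa_mean_yr": sa.mean,
                        "soc_stock_kg_m2": soc_stock,
                        "decomposability_ugC_gSOC_h": decomp,
                        "roc_pct": roc,
                        "lag_years": 0,
                    }
                )
    return SyntheticTruth(table=pd.DataFrame(rows), config=config, seed=seed)


def synth_observations(
    truth: SyntheticTruth,
    record: AtmosphericRecord,
    config: Optional[SyntheticConfig] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Forward-simulate noisy Δ¹⁴C observation pairs from the truth table.

    Each layer's (Δ¹⁴C_bulk, Δ¹⁴C_respired) is predicted at its
    observation year and perturbed with independent Gaussian noise at the
    configured measurement uncertainties. δ¹³C columns are plant-like
    (≈ −27 ‰) unless the row is carbonate-injected: the first
    ``len(config.carbonate_fractions)`` rows mix a ¹⁴C-free, δ¹³C-heavy
    carbonate endmember into the respired CO₂ at the known fraction, so
    the screening stage can be exercised against ground truth.
    """
    config = truth.config if config is None else config
    seed = (truth.seed + 1) if seed is None else seed
    rng = np.random.default_rng(seed)
    rows = []
    for i, row in truth.table.reset_index(drop=True).iterrows():
        p = TwoPoolSeriesParams(row.k_fast, row.k_slow, row.alpha)
        obs_year = float(row.obs_year)
        if obs_year > record.end_year:
            raise ValueError(
                f"obs_year {obs_year} outside atmospheric record "
                f"({record.start_year}-{record.end_year})"
            )
        bulk, resp = forward_delta14c(p, record, obs_year)
        d14c_soc = bulk + rng.normal(0.0, config.sd_soc_permil) if config.sd_soc_permil else bulk
        d14c_co2 = resp + rng.normal(0.0, config.sd_co2_permil) if config.sd_co2_permil else resp
        d13c_soc = float(rng.normal(-27.0, 0.8))
        if i < len(config.carbonate_fractions):
            f = config.carbonate_fractions[i]
            d14c_co2 = (1.0 - f) * d14c_co2 + f * (-1000.0)
            d13c_co2 = d13c_soc + f * (config.d13c_carbonate - d13c_soc)
        else:
            d13c_co2 = d13c_soc
        rows.append(
            {
                "site": row.site,
                "land_use": row.land_use,
                "depth_top_cm": row.depth_top_cm,
                "depth_bottom_cm": row.depth_bottom_cm,
                "organic_layer": row.organic_layer,
                "obs_year": int(obs_year),
                "d14c_co2_permil": d14c_co2,
                "sd_co2_permil": config.sd_co2_permil or 2.0,
                "d14c_soc_permil": d14c_soc,
                "sd_soc_permil": config.sd_soc_permil or 7.0,
                "d13c_co2_permil": d13c_co2,
                "d13c_soc_permil": d13c_soc,
                "soc_stock_kg_m2": row.soc_stock_kg_m2,
                "decomposability_ugC_gSOC_h": row["decomposability_ugC_gSOC_h"],
                "roc_pct": row.roc_pct,
                "lag_years": int(row.lag_years),
            }
        )
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)
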