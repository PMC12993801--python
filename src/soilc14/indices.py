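"""SOC vulnerability index, profile-weighted ages, depth-rate regressions
and land-use summary tables.

The vulnerability index relates SOC persistence (system age) to thermal
stability (%-ROC, the SOC fraction oxidised between 400 °C and 600 °C):

    VI = ln(1 + system age) / %-ROC,

with %-ROC on the 0–100 percent scale. VI ≈ 0.1 flags carbon that is both
persistent and stabilised; VI > 1.0 flags old carbon that lacks
stabilisation and is hence vulnerable to changed conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SoilLayerProperties",
    "VulnerabilityRecord",
    "vulnerability_index",
    "classify_vi",
    "profile_weighted_ages",
    "depth_rate",
    "depth_rates_by_landuse",
    "depth_midpoint",
    "assign_depth_bin",
    "landuse_summary",
    "DEPTH_BINS",
]

# sampling depth increments; ">40" runs to the per-site bottom depth (max 90 cm)
DEPTH_BINS: Tuple[str, ...] = ("OL", "0-5", "5-10", "10-20", "20-40", ">40")
_MINERAL_BIN_EDGES: Dict[Tuple[float, float], str] = {
    (0.0, 5.0): "0-5",
    (5.0, 10.0): "5-10",
    (10.0, 20.0): "10-20",
    (20.0, 40.0): "20-40",
}
_DEEP_BIN_TOP = 40.0
_DEEP_BIN_DEFAULT_MID = 65.0  # midpoint of 40-90 cm when actual bottom unknown


@dataclass(frozen=True)
class SoilLayerProperties:
    soc_stock_kg_m2: float
    decomposability_ugC_gSOC_h: float
    roc_pct: float
    c_to_n: float = math.nan
    d15n_permil: float = math.nan
    pedogenic_oxides_g_gsoc: float = math.nan
    clay_pct: float = math.nan
    ph: float = math.nan

    def __post_init__(self) -> None:
        if not math.isnan(self.roc_pct) and not 0.0 <= self.roc_pct <= 100.0:
            raise ValueError("roc_pct outside [0, 100]")
        if self.soc_stock_kg_m2 < 0:
            raise ValueError("soc_stock must be non-negative")


@dataclass(frozen=True)
class VulnerabilityRecord:
    sa_median_yr: float
    roc_pct: float
    vi: float


def vulnerability_index(sa_median_yr: float, roc_pct: float) -> float:
    """VI = ln(1 + system age)/%-ROC; NaN when %-ROC is zero or missing.

    The log damps the leverage of millennial subsoil and peat ages while
    spreading young litter-layer ages; the +1 keeps a one-year system age
    from mapping to zero.
    """
    if sa_median_yr < 0:
        raise ValueError("system age must be non-negative")
    if roc_pct is None or math.isnan(roc_pct) or roc_pct <= 0:
        return float("nan")
    return math.log1p(sa_median_yr) / roc_pct


def classify_vi(vi: float) -> str:
    """Interpretation band: ~0.1 persistent and stable, >1 vulnerable."""
    if math.isnan(vi):
        return "undefined"
    if vi > 1.0:
        return "persistent but lacks stabilization"
    if vi <= 0.3:
        return "persistent and stable"
    return "intermediate"


def profile_weighted_ages(
    layers: pd.DataFrame,
    tt_weight: str = "flux",
) -> Dict[str, float]:
    """Whole-profile transit time and system age from per-layer values.

    System age is weighted by each layer's SOC stock (columns
    ``sa_median_yr``, ``soc_stock_kg_m2``). Transit time is weighted by
    each layer's contribution to profile respiration: decomposability ×
    SOC stock under the default ``tt_weight="flux"`` interpretation, or
    decomposability alone with ``tt_weight="decomposability"``. Layers
    whose respired-CO₂ constraint was excluded (``excluded`` column) drop
    out of the transit-time average and are counted in ``n_tt_dropped``.
    """
    if tt_weight not in ("flux", "decomposability"):
        raise ValueError("tt_weight must be 'flux' or 'decomposability'")
    out: Dict[str, float] = {}

    sa_rows = layers.dropna(subset=["sa_median_yr", "soc_stock_kg_m2"])
    if len(sa_rows) == 0 or sa_rows["soc_stock_kg_m2"].sum() == 0:
        out["sa_profile_yr"] = float("nan")
        out["sa_reason"] = "no usable layers for stock weighting"
    else:
        w = sa_rows["soc_stock_kg_m2"].to_numpy()
        out["sa_profile_yr"] = float(
            np.average(sa_rows["sa_median_yr"].to_numpy(), weights=w)
        )

    tt_rows = layers.copy()
    if "excluded" in tt_rows.columns:
        dropped = int(tt_rows["excluded"].fillna(False).sum())
        tt_rows = tt_rows[~tt_rows["excluded"].fillna(False)]
    else:
        dropped = 0
    out["n_tt_dropped"] = dropped
    tt_rows = tt_rows.dropna(
        subset=["tt_median_yr", "decomposability_ugC_gSOC_h", "soc_stock_kg_m2"]
    )
    if len(tt_rows) == 0:
        out["tt_profile_yr"] = float("nan")
        out["tt_reason"] = "all layers excluded or missing"
    else:
        if tt_weight == "flux":
            w = (
                tt_rows["decomposability_ugC_gSOC_h"]
                * tt_rows["soc_stock_kg_m2"]
            ).to_numpy()
        else:
            w = tt_rows["decomposability_ugC_gSOC_h"].to_numpy()
        if w.sum() == 0:
            out["tt_profile_yr"] = float("nan")
            out["tt_reason"] = "zero total weight"
        else:
            out["tt_profile_yr"] = float(
                np.average(tt_rows["tt_median_yr"].to_numpy(), weights=w)
            )
    return out


def depth_rate(midpoints_cm: Sequence[float], ages_yr: Sequence[float]) -> float:
    """OLS slope of age on mineral-soil depth midpoint, yr cm⁻¹.

    Returns NaN with fewer than two layers; organic layers must be
    excluded by the caller (they have no meaningful mineral depth).
    """
    x = np.asarray(midpoints_cm, dtype=float)
    y = np.asarray(ages_yr, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2 or np.ptp(x) == 0:
        return float("nan")
    return float(stats.linregress(x, y).slope)


def depth_rates_by_landuse(
    df: pd.DataFrame, age_col: str
) -> Tuple[pd.Series, float]:
    """Per-land-use depth slopes of ``age_col`` and their across-use mean.

    Mineral layers only (``organic_layer`` rows are dropped); the headline
    rate is the unweighted mean of the per-land-use slopes.
    """
    mineral = df[~df.get("organic_layer", pd.Series(False, index=df.index)).fillna(False)]
    slopes = mineral.groupby("land_use", sort=True).apply(
        lambda g: depth_rate(g["depth_mid_cm"], g[age_col]),
        include_groups=False,
    )
    return slopes, float(np.nanmean(slopes.to_numpy()))


def depth_midpoint(
    top_cm: float, bottom_cm: float, organic_layer: bool = False
) -> float:
    """Arithmetic midpoint of a mineral layer; the >40 cm layer uses the
    actual bottom depth when given, else 65 cm; organic layers → NaN."""
    if organic_layer:
        return float("nan")
    if top_cm >= _DEEP_BIN_TOP and (bottom_cm is None or math.isnan(bottom_cm)):
        return _DEEP_BIN_DEFAULT_MID
    return 0.5 * (top_cm + bottom_cm)


def assign_depth_bin(
    top_cm: float, bottom_cm: float, organic_layer: bool = False
) -> str:
    """Map a sampled layer to the standard depth bins by exact interval match."""
    if organic_layer:
        return "OL"
    key = (float(top_cm), float(bottom_cm))
    if key in _MINERAL_BIN_EDGES:
        return _MINERAL_BIN_EDGES[key]
    if float(top_cm) == _DEEP_BIN_TOP and float(bottom_cm) <= 90.0:
        return ">40"
    raise ValueError(
        f"layer ({top_cm}, {bottom_cm}) cm does not match a standard depth bin"
    )


def landuse_summary(
    fits: pd.DataFrame,
    value_cols: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Mean ± SD per land use × depth bin (Table-style summary).

    ``fits`` needs ``land_use``, ``depth_top_cm``, ``depth_bottom_cm``,
    ``organic_layer`` and the value columns (default: the Δ¹⁴C pair and
    median ages). Cells with a single observation report the mean with a
    missing SD; empty cells are absent from the output.
    """
    if value_cols is None:
        value_cols = [
            c
            for c in (
                "d14c_co2_permil",
                "d14c_soc_permil",
                "tt_median_yr",
                "sa_median_yr",
            )
            if c in fits.columns
        ]
    df = fits.copy()
    bad_rows = []
    bins = []
    for i, row in df.iterrows():
        try:
            bins.append(
                assign_depth_bin(
                    row["depth_top_cm"],
                    row["depth_bottom_cm"],
                    bool(row.get("organic_layer", False)),
                )
            )
        except ValueError:
            bad_rows.append(i)
            bins.append(None)
    if bad_rows:
        raise ValueError(f"rows with unknown depth interval: {bad_rows}")
    df["depth_bin"] = pd.Categorical(bins, categories=DEPTH_BINS, ordered=True)

    records = []
    for (lu, dbin), grp in df.groupby(["land_use", "depth_bin"], observed=True):
        rec: Dict[str, object] = {"land_use": lu, "depth_bin": dbin, "n": len(grp)}
        for col in value_cols:
            vals = grp[col].dropna().to_numpy()
            rec[f"{col}_mean"] = float(vals.mean()) if vals.size else float("nan")
            rec[f"{col}_sd"] = (
                float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
            )
        records.append(rec)
    return (
        pd.DataFrame.from_records(records)
        .sort_values(["land_use", "depth_bin"])
        .reset_index(drop=True)
    )
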