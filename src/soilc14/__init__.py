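"""Radiocarbon-constrained two-pool soil carbon modelling.

Fits a fast/slow series compartmental model to paired Δ¹⁴C observations
of incubation-respired CO₂ and bulk SOC, derives transit-time and
system-age distributions with MCMC uncertainty, and computes a SOC
vulnerability index relating persistence to thermal stability.
"""

from importlib import resources

from .radiocarbon import (
    LAMBDA_14C,
    REFERENCE_YEAR,
    AtmosphericRecord,
    delta_from_fm,
    equilibrium_fm,
    fm_from_delta,
    load_atmospheric_record,
)
from .twopool import (
    AgeDistribution,
    CompartmentSystem,
    PoolStocks,
    TwoPoolSeriesParams,
    forward_delta14c,
    forward_fm,
    steady_state,
    system_age_distribution,
    transit_time_distribution,
)
from .calibration import (
    AgeUncertainty,
    ObservationRecord,
    PosteriorChain,
    PriorBounds,
    collinearity_index,
    cost,
    default_init,
    fit_least_squares,
    run_mcmc,
    summarize_posterior_ages,
)
from .screening import (
    CarbonateAssessment,
    IncubationSeries,
    correct_d14c_co2,
    decomposability,
    estimate_carbonate_fraction,
    screen_observations,
)
from .indices import (
    assign_depth_bin,
    classify_vi,
    depth_midpoint,
    depth_rate,
    depth_rates_by_landuse,
    landuse_summary,
    profile_weighted_ages,
    vulnerability_index,
)
from .synthetic import (
    SyntheticConfig,
    SyntheticTruth,
    synth_atmosphere,
    synth_observations,
    synth_sites,
)
from .pipeline import fit_row, fit_table, observation_from_row

__version__ = "0.1.0"


def packaged_atmosphere() -> AtmosphericRecord:
    """The packaged synthetic bomb-curve fixture (no download required)."""
    path = resources.files("soilc14").joinpath("data/atmosphere_synthetic.csv")
    with resources.as_file(path) as p:
        return load_atmospheric_record(p, zone_label="packaged synthetic")
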