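# Methods

## Radiocarbon conventions

All ¹⁴C quantities use the Δ¹⁴C reporting convention: Δ¹⁴C =
(F·e^{λ(1950−y)} − 1)·1000 ‰, with F the absolute fraction modern, y the
collection year, and λ = 1/8267 yr⁻¹. −1000 ‰ is radiocarbon-free carbon.
Conversions round-trip to better than 1e-10 ‰ over Δ¹⁴C ∈ [−999, 1000] and
years 1900–2030 (property-tested).

The atmospheric record is regridded to integer years by linear
interpolation at load time; bomb-curve compilations are dense enough that
higher-order interpolation adds nothing. Before the record's first year
the atmosphere is held constant at its earliest value. That choice makes
the spin-up analytic: the pre-bomb equilibrium of a pool with rate k under
constant atmosphere F_atm is F_atm·k/(k+λ), chained through the two pools
(F_slow = F_fast·k_s/(k_s+λ)). This is exact for a constant pre-record
atmosphere and removes any long spin-up integration. Per-site bomb-curve
adjustments are exposed as a time lag (inputs in year y carry the
signature of year y − lag) and a constant ‰ offset, both defaulting to 0.

## Forward model

The ¹⁴C balance d¹⁴C/dt = I₁₄C(t) + (A − λI)·¹⁴C is advanced with an
exact annual propagator. A − λI is lower triangular, so its matrix
exponential has a closed form; with the atmosphere held constant within
each calendar year the inhomogeneous term integrates exactly, and the
two-pool recursion decouples into two scalar geometric recursions
evaluated with vectorised dot products. The scheme is stiff-safe (exact
for any k), reproducible, and ~100× faster than a generic ODE solver; the
test suite keeps an explicit-Euler integrator (12 substeps/yr) as an
independent oracle, with agreement required to 0.5 ‰. When |k_f − k_s|
falls below 1e-6 relative, closed forms switch to their analytic limits
(Erlang for the hypoexponential, the confluent propagator entry) to avoid
cancellation.

Bulk Δ¹⁴C is the stock-weighted pool signature. Respired Δ¹⁴C is weighted
by the release fluxes (1−α)·k_f·C_f and k_s·C_s — in the series structure
only the non-transferred share of fast-pool turnover leaves the system.

## Age distributions

At steady state the transit-time density is the phase-type form
−1ᵀA e^{At}u/‖u‖, which for this topology reduces to the mixture
(1−α)·Exp(k_f) + α·Hypoexp(k_f, k_s); the system-age density is
1ᵀe^{Aa}u/‖x*‖, the stock-weighted analogue. The implementation uses the
closed-form mixtures; matrix-exponential evaluation is kept in the tests
as the oracle (pointwise agreement to 1e-8 over a 100-point random
parameter grid). Means are closed-form (E[TT] = 1/k_f + α/k_s = stock/input,
the throughput identity, verified to 1e-10). Medians and quartiles invert
the closed-form CDF by bracketed Brent root-finding (bracket grown
geometrically from 1/min(k), tolerance 1e-10 relative). Both
distributions are right-skewed for every admissible parameter set with
k_s ≤ k_f, so the median < mean ordering is asserted for every posterior
draw rather than spot-checked.

## Calibration

Each layer contributes two constraints (Δ¹⁴CO₂, Δ¹⁴C-SOC) against three
parameters (k_f, k_s, α). The cost is the inverse-variance weighted sum of
squared residuals; σ defaults to 2 ‰ for respired CO₂ (gas-source AMS)
and 7 ‰ for bulk SOC (EA-AMS, mid-range of 6–8 ‰) when the table carries
no per-row uncertainty.

* **Priors** (config-exposed): log-uniform k_f ∈ [1e-3, 10] yr⁻¹,
  log-uniform k_s ∈ [1e-6, 1] yr⁻¹, uniform α ∈ [0, 1], with k_s ≤ k_f to
  fix the fast/slow labelling. The ranges span litter-like to millennial
  turnover.
* **Initialisation**: a coarse log-grid search (6 × 8 × 3 points) stands
  in for a manual first guess, then trust-region least squares in
  (ln k_f, ln k_s, logit α).
* **MCMC**: adaptive Metropolis in (ln k_f, ln k_s, α) — uniform prior in
  those coordinates — for 10,000 iterations. The proposal covariance is
  re-estimated from the chain history every 100 iterations after the
  first 500, scaled by 2.38²/3. On a first-stage rejection, one
  delayed-rejection stage proposes from the same covariance shrunk ×0.2
  and accepts with the standard DR correction, preserving the target.
  Chains are byte-identical under a fixed seed. The sampler was validated
  against an independent affine-invariant ensemble sampler on the same
  posterior (central quantiles of derived ages agree within a few
  percent).
* **Burn-in** 20%; age uncertainty from 200 posterior parameter sets
  drawn without replacement, each propagated through the analytic
  distributions; point value = median of per-sample medians, uncertainty
  = SD across samples.

### Equifinality

With two constraints the zero-cost parameter set is a one-dimensional
manifold, and derived ages vary along it: two parameter sets can
reproduce the same observation pair to 1e-11 ‰ yet differ twofold in
median system age. Point estimates therefore inherit the prior's weight
along the ridge, and posterior medians of derived ages can sit well away
from any particular generating parameter set even with noiseless data.
The package treats the posterior interval, not the point value, as the
deliverable: under the study's noise levels the 5–95% interval of median
system age covers the generating value in >80% of synthetic layers. The
per-fit collinearity index (full three-parameter set is rank-deficient by
construction; the reported value is the worst two-parameter subset)
flags how severe the degeneracy is near the optimum.

## Screening and covariates

Carbonate admixture in respired CO₂ is estimated by two-endmember δ¹³C
mixing, with the biogenic endmember taken from the same layer's bulk-SOC
δ¹³C and the carbonate endmember at 0 ‰ (δ¹³C) and −1000 ‰ (Δ¹⁴C),
standard values for geogenic carbonate. For f ≤ 5% the measured Δ¹⁴CO₂ is
unmixed, (Δ_meas − f·Δ_carb)/(1−f); above 5% the respired-CO₂ constraint
is excluded. The correction exactly inverts the mixing model
(property-tested to 1e-10 ‰). SOC decomposability is total incubation
CO₂-C per g SOC per hour.

## Aggregation

* VI = ln(1 + median system age)/%-ROC with %-ROC on the 0–100 scale —
  the printed threshold bands (~0.1 stable, >1 vulnerable) are only
  consistent with the percent scale. %-ROC = 0 yields a missing value,
  not infinity.
* Profile system age weights layers by SOC stock; profile transit time
  weights layers by their respiration-flux contribution, decomposability
  × SOC stock (a per-gram-decomposability weighting is available as
  `tt_weight="decomposability"`). Layers whose respired-CO₂ constraint
  was excluded drop out of the transit-time average only.
* Depth rates are OLS slopes of age on mineral-layer midpoints (organic
  layers excluded), per land use, averaged across land uses for the
  headline. The >40 cm layer uses its actual bottom depth when known,
  else a 65 cm midpoint (sampling stops at 90 cm).
* Summary tables report mean ± sample SD per land use × depth bin
  (OL/0–5/5–10/10–20/20–40/>40); singleton cells report a missing SD.

## Synthetic study design

The generator's defaults are the study conditions: 19 sites (4 temperate
grassland, 4 alpine grassland, 5 forest, 3 cropland, 3 managed peatland),
five mineral depth increments everywhere plus an organic layer in
forests; observation year 2023 (2022 for alpine sites, sampled a year
earlier). True rates are drawn log-uniformly within per-land-use topsoil
ranges and slowed with depth (×1 → ×0.1 from 0–5 to 40–90 cm); managed
peatlands draw k_s ∈ [1e-4, 4e-4] yr⁻¹, giving millennial system ages
throughout. Covariates follow monotone depth trends with lognormal
scatter — SOC stock and decomposability decline with depth, %-ROC rises
with depth except in peatlands where it stays uniformly low. Measurement
noise is independent Gaussian, σ = 2 ‰ (CO₂) and 7 ‰ (SOC), the marginal
measurement uncertainties of the two AMS routes. Carbonate-contaminated
layers can be injected at known fractions to exercise screening end to
end.

The packaged bomb-curve fixture (constant −5 ‰ baseline, linear rise
1955–1964 to +700 ‰, exponential relaxation with τ = 16 yr) reproduces
the shape of Northern-Hemisphere compilations so that no download is ever
needed; real records load through the same CSV interface. What the
generator does not emulate — and what passing tests therefore do not
demonstrate about field data: spatial autocorrelation among sites,
non-steady-state land-use history, seasonal input variability, deviations
of the real bomb curve from the parametric shape, and incubation
artefacts (priming, moisture effects). Tests on synthetic data validate
the machinery and its statistical calibration, not the field inference.

## Problem sizes and numerical choices

The shipped analysis and the acceptance run fit the full 100-layer
synthetic campaign with 10,000-iteration chains; test-suite experiments
use 50 layers for the coverage check and shorter chains (400–4,000
iterations) where only determinism or internal consistency is at stake.
Density normalisation is verified by adaptive quadrature to 1e-6;
degenerate inputs (α = 0, k_f = k_s, f_carbonate ∈ {0, 1}, zero %-ROC,
single-layer profiles) all have defined, tested behaviour. Known
limitations: two-pool series topology only (no parallel or feedback
structures, no ≥3-pool models), steady state assumed everywhere, one
observation time point per layer, and no hierarchical pooling across
sites.
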