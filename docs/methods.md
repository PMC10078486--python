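# Methods

## Model structure

Canopy isoprene flux is computed as the product
F = ε · LAI · γ_P · γ_T · γ_A · γ_SM · γ_C. The package authors the
drought factor γ_SM and the indicator pipeline that feeds it; the light
and temperature factors use the canonical MEGAN v2.1 isoprene forms so
that the product is computable in an offline, single-point setting:

* γ_P = C_P·αQ/√(1+α²Q²) with α = 0.004, C_P = 1.21 (Q = PPFD in
  µmol m⁻² s⁻¹), normalized so Q = 1000 gives ≈1.17;
* γ_T is the two-constant (CT1 = 95, CT2 = 230) peaked response with
  optimum T_opt = 313 + 0.6(T₂₄₀ − 297) K and peak
  E_opt = 2.034·e^{0.05(T₂₄ − 297)}·e^{0.05(T₂₄₀ − 297)}, where T₂₄ and
  T₂₄₀ are causal running means of leaf temperature over the past 24 h
  and 240 h (expanding windows at the start of a series; future samples
  can never affect the current flux). At standard conditions (leaf 303 K,
  history 297 K) γ_T ≈ 1.00.

Leaf temperature is approximated by air temperature plus a configurable
constant offset (default 0): the offline drought path deliberately embeds
leaf-temperature effects inside γ_lt rather than simulating a leaf energy
balance. γ_A and γ_C default to 1 (constant canopy age structure, fixed
CO₂) with config hooks. The default emission factor is the canopy-scale
ε = 10 mg m⁻² h⁻¹; 2.45 mg m⁻² h⁻¹ is the documented leaf-scale
alternative.

## Drought indicator (f_PET)

ET = LE/λ with λ = 2.501 − 0.00237·T MJ kg⁻¹; PET is the Penman–Monteith
reference form with the sub-daily aerodynamic coefficient 37/(T+273.15),
applied per half-hour sample. Energy fluxes in W m⁻² are converted to
MJ m⁻² day⁻¹ (×0.0864) so ET and PET share mm day⁻¹. The saturation
vapor pressure, its slope, and the psychrometric constant use the FAO-56
Tetens conventions (e_s = 0.6108·exp(17.27T/(T+237.3)),
Δ = 4098·e_s/(T+237.3)², γ = 0.000665·P); note the conventional 4098
rounds the exact 17.27·237.3, an ~4×10⁻⁵ relative difference.

Pipeline: the per-sample ratio f = ET/PET is retained only on
"relatively sunny" samples (SW_in > 500 W m⁻², configurable) and only
where PET ≥ 0.05 mm day⁻¹ (ratio stability floor); the vapor pressure
deficit and PET are clipped at 0. Within each day, filtered samples are
filled with the mean of the day's retained ratios — equivalently the
daily value is the mean over retained samples; the fill is applied to the
ratio, not to ET and PET separately. Days with no retained sample are
missing. The daily series is smoothed with a centered 7-day running mean
(shrinking windows at the edges, missing days skipped), then min/max
normalized to [0, 1] and clipped; a config switch disables clipping for
response curves that tolerate indices slightly above 1. The upper bound
can be supplied directly or taken as a percentile (default 95th, linear
interpolation between order statistics) of a multi-year reference history
of the smoothed series.

The CLM-style water stress function β_t = Σ wᵢrᵢ, with per-layer wilting
factor w = [(ψ_c − ψ)/(ψ_c − ψ_o)]·[(θ_sat − θ_ice)/θ_sat] clipped to
[0, 1], is provided for the explicit path. Matric potentials are in mm
and negative under tension (ψ_c < ψ_o ≤ 0).

## Drought activity factors

PDS: γ_SM = γ_sm_max·γ_sub·γ_lt as in the README, defaults
a1 = −7.45, a2 = −28.76, b1 = 3.26, b2 = 2.35×10⁶, γ_sm_max = 1.4. The
index argument is clipped to [0, 1] by default (the normalized-index
convention), with a switch exposing the extended [0, 1.3] domain implied
by the 1.3 offset in γ_lt. The curve has a ~7×10⁻⁴ local dip just below
index 1 (the γ_sub and γ_lt tails cross); it is real, not numerical
noise.

EDS: the middle branch Vcmax/α can exceed 1 for large Vcmax and is
clipped to [0, 1], since the severe-drought branch models a reduction.
The jump at β_t = 0.6 is part of the formulation and is left as is.

Legacy forms: the linear ramp uses closed boundaries (θ = θ_w → 0,
θ = θ_c → 1); ramp widths 0.06 (v2), 0.04 (v2.1), 0.07 with a 0.4 power
(power-law variant). The Gompertz-type soil-water-availability form is
implemented exactly as published even though it evaluates to ≈0.19 at
SWA = 1, far from a neutral factor; a `rescale` flag divides by that
value for side-by-side comparison. SWA = (θ − θ_w)/(θ_max − θ_w),
unclipped by default.

## Calibration

Observed activity ratios γ_sm_obs = F_obs/F_mod are formed only where the
drought-free modeled flux exceeds 0.5 mg m⁻² h⁻¹ (excludes nights and
dawn, where the ratio is unstable). Ratios are grouped into 0.05-wide
index bins; per-bin means and quartiles are recorded, and all bin
statistics are divided by the mean of the highest-index retained bin so
the no-drought bin is exactly 1.

The fit is nonlinear least squares of the PDS curve against the
normalized bin means, with two numerical choices that matter:

* the model prediction is normalized at the reference bin exactly as the
  data is — the residual compares γ(x; p)/γ(x_ref; p) with the
  normalized means — so the first-bin normalization injects no scale
  bias into the recovered curve (without this, recovery carries an
  irreducible ~0.7% offset because γ(x_ref) ≠ 1);
* the abscissa of each bin is the mean observed index of its samples,
  not the bin's geometric center, which removes the attribution bias for
  unevenly filled bins.

b2 spans many orders of magnitude and is fitted as log₁₀ b2; bounds keep
a1, a2 < 0, b1, b2 > 0 and γ_sm_max ∈ [1, 3]. 95% confidence half-widths
come from the first-order parameter covariance. Because (b1, a1) and
(b2, a2) trade off against the fixed 0.2 and 1.3 offsets, the
parameterization is not fully identifiable; fit quality is therefore
always judged on the fitted curve (sup-norm over [0, 1]), never on raw
parameter values. An unweighted fit on bin means is the default
(matching the binned construction); inverse-IQR weighting is available.
Non-convergence is reported in the result, never silent.

Evaluation statistics are MB = mean(mod − obs), ME = mean|mod − obs|,
RMSE, and R² as the squared Pearson correlation (flagged NaN for constant
series). Daytime presentation uses a centered 9-sample running mean
applied within each calendar day's daytime block (daytime = SW_in >
10 W m⁻² where a mask is derivable; night samples never enter window or
output).

## Synthetic forcing

The generator emulates a mid-latitude deciduous-forest growing season
with one drought episode, in the spirit of a 2012-style drought campaign:
92 days (June–August) at 30-minute cadence; sinusoidal diurnal shortwave
(clear-sky noon peak 900 W m⁻², daylight 06–18) with PPFD = 2.1·SW; a
diurnal temperature cycle (mean 24 °C, half-amplitude 7 °C) elevated by
up to 5 °C at full drought depth; air humidity and soil moisture
(0.40 → 0.21 m³ m⁻³) declining with the index. The daily drought index
follows a trapezoid: 1 outside the 30-day window, ramping over 7 days to
a floor of 0.3. The latent heat flux is back-computed from each sample's
own PET so that ET/PET equals the day's prescribed index (2% seeded
within-day scatter, capped at 1 so ET ≤ PET on sunny samples) — running
the f_PET pipeline on the generated series recovers the prescribed
trajectory up to smoothing error. Pseudo-observations multiply a
drought-free model run by the PDS response at the day's index and by
mean-one lognormal noise (σ = 0.15 by default, a typical eddy-flux
relative error).

What the generator does not emulate: real solar geometry and cloud
fields, energy-balance non-closure, gap structure of real towers,
advection, species composition. Passing round-trip and calibration tests
on this forcing therefore demonstrates the internal consistency of the
pipeline and the recoverability of the response curve under the stated
noise — not skill against field observations, which requires real
flux-tower data.

## Problem sizes and determinism

The default test and demonstration scenario is the 92-day half-hourly
season above (4 416 samples); the Monte-Carlo calibration check uses 20
replicates at 15% noise. Dense curve evaluations use 10⁴–10⁵ point
grids. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical inputs and seeds produce
bit-identical outputs, including CSV round-trips at the documented
6-significant-digit precision.

## Known limitations

* No canopy radiative transfer or leaf energy balance: leaf temperature
  is air temperature plus an offset, so the γ_lt stimulation is carried
  entirely by the calibrated curve rather than by simulated physics.
* The EDS path here broadcasts a supplied β_t series with a constant
  Vcmax; it does not couple to a host land model.
* No gap-filling of meteorology beyond the stated within-day ratio fill,
  and no energy-balance-closure correction of LE.
* Single site, single species mix: the default PDS parameters encode one
  temperate deciduous forest's drought season and should be recalibrated
  for other ecosystems.
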