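# Methods

`resflux` reduces four kinds of reservoir methane monitoring streams to
fluxes, fills the gaps in the eddy-covariance (EC) record with a neural
network ensemble, and combines everything into whole-reservoir annual
emission estimates.  This note documents the models, the choices made
where the procedure was genuinely open, and what the synthetic test bed
does and does not demonstrate.

## Measurement reduction

**Funnel traps.** An active funnel trap (AFT) collects rising bubbles
under a funnel of cross-section `A_F` (0.3 m²); a differential-pressure
sensor logs the gas column in the collection tube every 5 min.  Voltage
maps to gas-column height through a linear laboratory calibration
(`height_cm = circ_volt * m + b`, default slope 31 cm/V with 0.31 cm/V
slope error), and height to volume through the tube cross-section
(`aft_d`, default 0.10 m; the diameter is a required calibration input —
it is instrument-specific and has no universal default).  Volumes are
smoothed with a centered 12-point (60-min) moving average; edge windows
shrink rather than drop records.  Siphon purges appear as negative steps
an order of magnitude larger than any bubble increment; the default
detection threshold is 5x the 95th percentile of positive per-step
increments.  Because the centered moving average smears a purge across
the averaging window, contiguous flagged steps are merged into one purge
event, and the excluded increments are replaced by the local
accumulation rate (mean of non-purge steps within ±2 h on each side)
rather than zero — dropping them loses the gas that arrives while the
siphon fires and biases the seasonal mass balance low by several
percent.  Flux is the volume increment over a right-closed rolling bin
(default 2 h, labeled by end time) times the bubble-gas CH4
concentration, divided by elapsed time and funnel area.

**Trap uncertainty.** The per-flux error treats a bin as the difference
of two smoothed readings, each carrying the offset-voltage SD and
electronic noise through the height calibration, plus relative slope and
gas-concentration errors.  For cumulative emissions the terms separate
by correlation structure: electronic noise is independent per bin and
accumulates over non-overlapping bins only; slope and concentration
errors are fully correlated and act as relative errors on the seasonal
total; the offset re-zeroing uncertainty and a fixed 2 mL dead volume
enter once per siphon purge cycle.  Treating the offset SD as
independent per bin instead would inflate a ~30 g m⁻² season's error to
±16 g m⁻², an order of magnitude beyond what a trap of this design
actually delivers.

**Chambers.** The headspace CH4 mixing ratio under a floating chamber
rises at `dchi/dt`; the diffusive flux follows from the ideal gas law,
`F = (dchi/dt)(V/A)(P/RT)`, converted with the CH4 molar mass
(16.04 g mol⁻¹).  Two rate models are fitted: linear, and a saturating
exponential `chi(t) = chi_eq + (chi0 − chi_eq) exp(−kt)` whose t = 0
derivative is the reported rate (the surface flux before headspace
feedback suppresses it).  The saturating form is the physically expected
headspace-equilibration response.  Model choice is by AIC with a
parsimony margin: the saturating model nests the linear one (k → 0), so
a bare AIC comparison endorses spurious curvature on noisy linear traces
about 16 % of the time (the χ²₁ > 2 null probability); requiring the
extra parameter to win by 4 AIC units brings family selection above 95 %
at SNR ≥ 10 without affecting genuinely curved traces, whose AIC
advantage is orders of magnitude larger.  Fits with r² ≤ 0.9 are
rejected — this is why weak fluxes (≲ 0.5 mg CH4 m⁻² h⁻¹ for the default
geometry and a 0.05 ppm analyzer noise over a 5-min deployment) are
reported as rejected deployments rather than numbers.  Ebullition spikes
are screened before fitting: any single-step increase beyond 5x the
robust local slope scale (the larger of the median step and the
MAD-based step spread) invalidates the deployment.

**EC quality control.** Records above quality level 1 on the 0–2
integrated turbulence/stationarity scale are rejected.  At the
near-shore tower (S1) winds from the land sector — the closed interval
[195°, 33°] wrapping through north — are rejected; endpoints are
rejected as the conservative reading of an interval whose inclusivity is
not specified.  At the open-water tower (S2) records with friction
velocity u* < 0.07 m s⁻¹ are rejected; the boundary value is retained.
Driver gaps are filled two ways: variables with a weather-station
analogue (temperatures, wind, pressure) by station substitution after a
linear cross-calibration fitted on the overlap; turbulent-flux variables
(LE, H, u*) by the mean diurnal course — the mean of valid values at the
same half-hour of day within ±7 days, doubling the window to a ±28-day
cap until at least 3 donors exist.  Static pressure over the sediment is
atmospheric pressure plus `rho g h` with density fixed at 1000 kg m⁻³
(the temperature effect is < 0.3 % over 0–30 °C).

## Gap filling

Missing 30-min fluxes are predicted by ensembles of single-hidden-layer
feed-forward networks ("5–20 layers" in the source description is read
as 5–20 hidden units in one layer: 16 sizes x 50 random starts gives the
stated 800 models per ensemble).  Drivers are standardized; hour of day
and day of year enter as sine/cosine pairs; a site indicator is included
when present.  Observed records are split 60/20/20 into
train/test/validation (fractions were not specified), stratified by
k-means clusters (k = 10, drivers only) so every driver regime is
represented proportionally in every split.  Per ensemble the best
`top_k` models by test R² are kept and their median is the ensemble
prediction; the whole procedure repeats over `n_resamplings` re-splits.
Each gap receives the median of the ensemble medians; the 95 % CI is the
2.5/97.5 percentile band of those medians; the bias error is the mean
validation residual (prediction − observation), converted to an
accumulated mass by multiplying by the gap count and the 0.5 h record
length.  Driver importance is permutation importance on the test split
(sin/cos pairs permuted together), averaged over resamplings and
normalized to 100 % — the source defines a "variable importance factor"
without a formula, and permutation importance is the model-agnostic
choice.

Networks are trained with L-BFGS (small dense problems converge faster
and more reliably than SGD variants here) to a 500-iteration cap.  The
full-scale configuration (800 x 20) is available but expensive; the
reduced preset — 4 hidden sizes x 5 starts, top 10, 5 resamplings — is
the routine configuration and the one exercised by the tests.  The
reduced preset uses the larger end of the size range (8, 12, 16, 20):
the dominant failure mode at small sizes is smearing of the short spring
burst, whose Gaussian-pulse shoulders need localized day-of-year
response that 5–8 hidden units often cannot form.

## Upscaling

The reservoir is stratified at 3 m into shallow (0.8 km²) and deep
(1.6 km²) areas.  The EC record characterizes the shallow stratum.  The
deep stratum is the continuously monitored deep sentinel site (trap
ebullition plus interpolated chamber diffusion) scaled by the reservoir
ratio RR — the sentinel's total flux over the mean total flux of the
deep survey sites, computed at each survey and linearly interpolated to
daily resolution (constant extension outside the surveyed span).  Since
RR measures how far the sentinel sits above or below its stratum, the
stratum series is the sentinel series *divided* by RR.  Stratum
cumulative emissions are area-weighted into the whole-lake areal total;
mass in Mg follows from areal g m⁻² times area in km².  The survey-only
estimator applies the first survey's whole-lake mean back to 1 May, the
last forward to 15 October, interpolates between surveys, and assumes
zero flux outside that window (the trap+chamber estimator uses the same
winter-zero assumption; the EC estimator carries its own measured or
gap-filled winter values).  Survey means are inclusion-weighted; their
confidence intervals use the weighted-SRS variance — a stated
simplification standing in for the spatially balanced design's
local-neighborhood variance estimator, which belongs to the survey
design tool, not this package.  Independent error components combine in
quadrature throughout.

## Statistics

**Ecological Q10.** OLS of log10(flux) on temperature; ecoQ10 = 10^(10b).
Only this regression direction makes 10^(10b) the multiplicative change
per 10 °C.  Nonpositive fluxes are excluded and counted.  Time-indexed
inputs are aggregated to daily means by default (the ecosystem
temperature response is a slow signal; 30-min scatter only dilutes r²),
configurable off.

**2-D Kolmogorov–Smirnov breakpoint.** For each observed (temperature,
flux) point as candidate origin, the plane splits into four quadrants;
the statistic D is the largest absolute difference between the empirical
quadrant fraction and the product of the marginals, over all origins
(with ≤-based counting the four quadrant deviations coincide, so one
suffices).  The temperature of the maximizing origin is the breakpoint;
significance is by permutation of flux against temperature (999 default;
199 in fast paths).  The permutation test is exact up to Monte Carlo
error and its type-I rate calibrates to ~5 % at the 0.05 level.

**Diurnal classifier.** A day with ≥ 8 daytime and ≥ 8 nighttime
non-gap-filled records is "strong" when the day/night median contrast
exceeds 50 % of the smaller median magnitude *and* the series is smooth,
quantified as lag-1 autocorrelation ≥ 0.5 — a reproducible stand-in for
the visual smoothness screening the procedure otherwise requires.  A
zero smaller-median makes the ratio undefined; the fallback compares the
absolute median difference against the day's MAD.

**Dissolved CH4.** Headspace equilibration against CH4-free helium:
original concentration = (headspace moles by ideal gas + dissolved moles
by the Bunsen solubility coefficient) / water volume, with the standard
three-term freshwater CH4 solubility fit (valid 0–40 °C).  Defaults
match the 25 mL headspace / 115 mL water syringe protocol.

**Water-column stability.** Brunt–Väisälä N² = (g/ρ) dρ/dz by centered
differences on the thermistor depths, with the standard freshwater
density–temperature polynomial; statically unstable layers (negative N²)
are floored at zero for the reported maximum N.

## Synthetic test bed

The generator produces every stream from one truth: sediment temperature
(seasonal sinusoid peaking in late July + small diel cycle + AR(1)
noise) drives an exponential flux response `F = F0 * Q10^((T−T_thr)/10)`
above a threshold and flat baseline below, with a Gaussian-in-time
spring-burst pulse confined to the shallow stratum.  Defaults emulate
the study conditions: shallow Q10 35 above 22.5 °C, deep Q10 30 above
15 °C, baseline 1.5 mg m⁻² h⁻¹, burst peak 40 mg m⁻² h⁻¹ over 24 May–
4 June, ebullition 58 % / 88 % of the shallow/deep totals, 15 survey
sites, a 40 % EC gap fraction (half in half-day-to-3-day blocks, half
singletons — the real gap structure is described only by acceptance
percentages, so the block-length law is a free choice), and per-stream
Gaussian noise at realistic magnitudes (1.3 mg m⁻² h⁻¹ EC, 3 mV trap
electronics, 0.05 ppm analyzer).  The deep baseline multiplier (0.08)
keeps peak deep fluxes slightly below shallow ones, as observed, despite
the deep response's much wider above-threshold span.  Bubbles arrive as
an inhomogeneous Poisson process tracking the ebullitive truth, with
lognormal volumes (median 1 mL) — strictly positive and right-skewed —
and a 1 L siphon capacity, giving ~4.5 mL h⁻¹ mean accumulation,
consistent with a ~6 mg CH4 m⁻² h⁻¹ ebullitive flux through a 0.3 m²
funnel.

What passing tests show: the reduction formulas are exact inverses of
the generators at zero noise; the trap chain conserves injected gas mass
across purges to < 1 %; the gap filler recovers withheld truth (R² well
above 0.7 on the standard scenario) and its bias error is a fraction of
a percent of the cumulative; the breakpoint detector finds a constructed
threshold within sample spacing and holds its nominal type-I rate; a
shallow-only burst moves the hybrid whole-lake estimate far less than an
EC-only extrapolation.  What they do not show: robustness to real-data
pathologies absent from the generator — non-Gaussian and heteroscedastic
EC noise, driver measurement error, trap fouling and drift, footprint
variability, spatially structured survey noise, or bursts not expressible
as a smooth pulse.  Numbers produced on synthetic data characterize the
pipeline, not any particular reservoir.

## Problem sizes and numerical notes

Routine runs and the test suite use the reduced ensemble (20 networks x
5 resamplings on a 7-month, ~10,000-record season) and 199-permutation
breakpoint tests; the full-scale ensemble and 999 permutations are
configuration switches.  k-means uses 3 restarts; clusters with < 3
members merge into the nearest larger cluster.  Networks that fail to
converge rank at R² = −inf and are never selected.  Degenerate inputs
fail loudly: all-tied temperatures, empty validation sets, nonpositive
chamber durations, negative depths, purge thresholds ≤ 0.  Time handling
is UTC throughout; the only local-time concept (day/night labeling for
the diurnal classifier) is supplied by the caller.
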