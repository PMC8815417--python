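# resflux

Reservoir methane (CH4) emissions are dominated by two pathways —
steady diffusion across the air–water interface and episodic bubbling
(ebullition) from the sediment — and no single instrument sees both
everywhere.  `resflux` is a Python toolkit for teams that monitor a
reservoir with the usual combination of instruments and need one
defensible whole-lake annual emission number out of them:

* **eddy covariance (EC)** — 30-min, spatially integrated fluxes with
  quality flags, gappy by nature;
* **active funnel traps (AFT)** — continuous ebullition at fixed sites,
  logged as differential-pressure voltages with auto-purging siphons;
* **floating chambers** — short headspace deployments yielding one
  diffusive flux each;
* **spatially balanced whole-lake surveys** — 15-site snapshots of both
  pathways.

The package reduces each stream to fluxes with propagated uncertainty,
fills the EC gaps with a cluster-stratified ensemble of small neural
networks, scales everything to whole-reservoir emissions by a hybrid
stratified estimator, and quantifies the temperature response of the
fluxes.  A synthetic-data module generates all four streams from a known
ground truth so that the entire chain is testable without field data.

## The core quantities

**Trap reduction.**  Gas volume in the trap follows from the pressure
sensor voltage via the linear height calibration, then

    F_eb = ΔV · [CH4] / ((T_f − T_i) · A_F)

over 2-h rolling bins, with [CH4] the bubble-gas concentration and
`A_F` the funnel cross-section (0.3 m²).  Volumes are smoothed (12-point
moving average), siphon purges removed, and errors propagated by
root-sum-squares with the offset and dead-volume terms entering once per
purge cycle.

**Chamber reduction.**  `F = (dχ/dt)(V/A)(P/RT)`, with the rate from the
better of a linear and a saturating-exponential fit (AIC with a
parsimony margin); fits with r² ≤ 0.9 and spike-contaminated deployments
are rejected.

**Gap filling.**  Single-hidden-layer networks (sizes 5–20, 50 starts =
800 models per ensemble at full scale; best 100 kept) predict 30-min
fluxes from standardized drivers; 20 resamplings of the k-means-
stratified train/test/validation split give a median-of-medians filled
value, a percentile 95 % CI, and a validation bias error
`BE = mean(p − o)`.

**Upscaling.**  EC covers the shallow stratum (< 3 m, 0.8 km²); the deep
stratum (1.6 km²) is the continuously monitored deep sentinel site
scaled by the reservoir ratio RR (sentinel / deep-survey-site mean) at
each survey, interpolated daily.  Areal cumulatives are area-weighted;
mass in Mg = areal g m⁻² × area km².

**Temperature response.**  ecoQ10 = 10^(10b) for the OLS slope b of
log10(flux) on temperature, and a two-dimensional Kolmogorov–Smirnov
(2DKS) scan for the temperature at which the flux–temperature sample
departs most from independence, with a permutation p-value.

## Worked example

Reduce a simulated floating-chamber deployment (3.6 mg CH4 m⁻² h⁻¹ true
flux, 0.05 ppm analyzer noise):

```python
>>> from resflux.chamber_flux import (ChamberGeometry, detect_spike,
...                                   fit_rate, diffusive_flux)
>>> from resflux.synthetic_data import SimConfig, gen_chamber_trace
>>> geom = ChamberGeometry(v=0.03, a=0.2, p=101325.0, t=293.15)
>>> dep = gen_chamber_trace(3.6, geom, SimConfig(seed=1))
>>> detect_spike(dep.trace)          # ebullition screening
(False, None)
>>> fit = fit_rate(dep.trace)
>>> fit.kind, round(fit.rate, 5), round(fit.r2, 3), fit.accepted
('linear', 0.01001, 0.995, True)
>>> round(diffusive_flux(fit.rate, geom), 2)
3.6
```

The fitted headspace rate (0.01 ppm s⁻¹) converts through the chamber
geometry and the ideal gas law to 3.6 mg CH4 m⁻² h⁻¹ — the generating
flux.  A passive overnight trap works the same way from a directly
measured volume:

```python
>>> from resflux.trap_flux import BubbleGas, pft_flux
>>> pft_flux(1.8e-4, BubbleGas(ch4_conc=4.0e5), deployment_hours=15.0, a_f=0.3)
16.0
```

i.e. 180 mL of bubble gas at 400 g CH4 m⁻³ collected over 15 h under a
0.3 m² funnel is an ebullitive flux of 16 mg CH4 m⁻² h⁻¹.

The full pipeline — synthesize, reduce, QC, gap fill, upscale,
temperature statistics — runs from the command line:

```
resflux run --seed 3 --scale test
resflux simulate --seed 3 --out streams/
resflux chamber fit trace.csv --volume 0.03 --area 0.2
resflux ec qc ec.csv --site S2 --ustar-min 0.07
resflux stats breakpoint pairs.csv --permutations 999
```

`resflux run` prints a stage-by-stage report: record counts, the EC
rejection ledger, gap-fill test R² and bias, reservoir-ratio anchors,
and a seasonal summary table (warm-season mean fluxes per pathway and
cumulative annual areal emissions per estimator).

## Layout

| module | contents |
| --- | --- |
| `resflux.synthetic_data` | ground-truth generator for all four streams |
| `resflux.trap_flux` | AFT/PFT reduction and trap error model |
| `resflux.chamber_flux` | chamber trace fitting and daily interpolation |
| `resflux.ec_qc` | EC filters, random-error summaries, driver filling |
| `resflux.ann_gapfill` | stratified ANN-ensemble gap filling |
| `resflux.upscale` | survey means, reservoir ratio, hybrid estimator |
| `resflux.fluxstats` | ecoQ10, 2DKS breakpoint, diurnal classifier, solubility, stability |
| `resflux.pipeline` / `resflux.cli` | end-to-end orchestration and the `resflux` command |

`docs/methods.md` documents the models, defaults, and design choices in
detail.
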