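"""Synthetic measurement streams with known ground truth.

Emulates the four monitoring streams of a small eutrophic reservoir —
30-min eddy-covariance (EC) methane fluxes, 5-min active funnel-trap
voltages, ~5-s floating-chamber headspace traces, and 15-site whole-lake
survey tables — driven by a common "truth": a seasonal + diel sediment
temperature forcing, an exponential temperature-flux response above a
threshold, and a transient spring-burst pulse confined to the shallow
stratum.  Every generator is deterministic given the configuration seed,
and the generating truth is returned alongside the observations so that
downstream reductions can be checked against it exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from resflux.constants import GRAVITY, P_ATM_STANDARD, RHO_WATER

__all__ = [
    "SimConfig",
    "TruthBundle",
    "TrapSimulation",
    "ChamberDeployment",
    "default_noise",
    "zero_noise",
    "sediment_temperature",
    "gen_drivers",
    "gen_true_flux",
    "gen_ec_observations",
    "gen_trap_voltage",
    "gen_chamber_trace",
    "gen_survey",
    "write_streams",
]

#: noise standard deviations per stream, in the stream's own units
_DEFAULT_NOISE: dict[str, float] = {
    "sed_t": 0.3,  # degC
    "air_t": 1.5,  # degC
    "le": 15.0,  # W m-2
    "h": 10.0,  # W m-2
    "wind": 0.8,  # m s-1
    "u_star": 0.03,  # m s-1
    "par": 60.0,  # umol m-2 s-1
    "depth": 0.05,  # m
    "p_atm": 150.0,  # Pa
    "ec": 1.3,  # mg CH4 m-2 h-1 (matches a typical 30-min random error)
    "trap_volt": 0.003,  # V electronic noise
    "chamber_ppm": 0.05,  # ppm
    "survey": 1.0,  # mg CH4 m-2 h-1 site-level noise
}


def default_noise() -> dict[str, float]:
    """Per-stream noise SDs used when none are supplied."""
    return dict(_DEFAULT_NOISE)


def zero_noise() -> dict[str, float]:
    """All-zero noise map, for exactness tests on the generators."""
    return {k: 0.0 for k in _DEFAULT_NOISE}


@dataclass
class SimConfig:
    """Parameters of the simulated study.

    Defaults emulate the monitored reservoir: a 2.4 km^2 lake with a
    shallow (< 3 m) stratum holding the EC tower, a warm-season flux
    response with ecological Q10 ~ 35 above a ~22.5 degC sediment
    temperature threshold in the shallow stratum (Q10 ~ 30 above ~15 degC
    in the deep stratum), a sub-two-week spring burst confined to the
    shallow stratum, ebullition carrying 58 % / 88 % of the shallow / deep
    total flux, and a 40 % gap fraction in the EC record.
    """

    seed: int = 0
    start: str = "2018-04-01"
    end: str = "2018-11-01"
    burst_amplitude: float = 40.0  # mg CH4 m-2 h-1 at burst peak
    burst_window: tuple[str, str] = ("2018-05-24", "2018-06-04")
    q10_true: float = 35.0
    threshold_temp_true: float = 22.5  # degC, shallow stratum
    q10_true_deep: float = 30.0
    threshold_temp_deep: float = 15.0  # degC
    baseline_flux: float = 1.5  # mg CH4 m-2 h-1 below threshold
    # deep-stratum baseline multiplier; the deep response climbs over a
    # much wider span above its lower threshold, so a small baseline
    # yields peak deep fluxes comparable to (slightly below) shallow ones
    deep_scale: float = 0.08
    gap_fraction: float = 0.4
    block_gap_share: float = 0.5  # share of gap records placed in blocks
    noise_sd: Mapping[str, float] = field(default_factory=default_noise)
    bubble_rate: float = 4.0  # events h-1 at the mean ebullitive flux
    bubble_volume_median: float = 1.0e-6  # m3 (1 mL)
    bubble_volume_sigma: float = 0.5  # lognormal shape parameter
    bubble_ch4_mg_m3: float = 4.0e5  # mg CH4 per m3 of bubble gas
    trap_capacity: float = 1.0e-3  # m3 of gas triggering a siphon purge
    n_sites: int = 15
    depth_cutoff: float = 3.0  # m separating shallow from deep sites
    max_depth: float = 8.0  # m
    ebullitive_share_shallow: float = 0.58
    ebullitive_share_deep: float = 0.88

    def __post_init__(self) -> None:
        if not 0.0 <= self.gap_fraction <= 1.0:
            raise ValueError("gap_fraction must be in [0, 1]")
        start, end = pd.Timestamp(self.start), pd.Timestamp(self.end)
        if end <= start:
            raise ValueError("end must be after start")
        b0, b1 = (pd.Timestamp(t) for t in self.burst_window)
        if b1 < b0:
            raise ValueError("burst_window must be ordered")
        if self.burst_amplitude != 0.0 and not (start <= b0 and b1 <= end):
            raise ValueError("burst_window must lie within the simulation span")
        noise = dict(self.noise_sd)
        if any(v < 0 for v in noise.values()):
            raise ValueError("noise SDs must be >= 0")
        # unknown keys fall back to defaults so partial maps are usable
        merged = default_noise()
        merged.update(noise)
        object.__setattr__(self, "noise_sd", merged)
        if self.bubble_rate < 0:
            raise ValueError("bubble_rate must be >= 0")
        if self.trap_capacity <= 0 or self.n_sites < 2:
            raise ValueError("trap_capacity > 0 and n_sites >= 2 required")

    def index_30min(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="30min", tz="UTC")

    def index_5min(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="5min", tz="UTC")


@dataclass
class TruthBundle:
    """Ground truth shared by all generated streams.

    ``flux`` holds the 30-min true flux series per stratum, split into
    diffusive and ebullitive components (mg CH4 m-2 h-1); components sum
    to the stratum total at every timestamp by construction.
    """

    drivers: pd.DataFrame
    flux: pd.DataFrame
    config: SimConfig

    def stratum_daily(self, stratum: str) -> pd.Series:
        """Daily-mean true total flux for ``stratum`` in {shallow, deep}."""
        return self.flux[f"{stratum}_total"].resample("1D").mean()


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float = 0.95) -> np.ndarray:
    """Autocorrelated Gaussian noise with stationary SD ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd * math.sqrt(1.0 - phi * phi), n)
    out = np.empty(n)
    acc = rng.normal(0.0, sd)
    for i in range(n):
        acc = phi * acc + innov[i]
        out[i] = acc
    return out


def sediment_temperature(index: pd.DatetimeIndex) -> np.ndarray:
    """Deterministic seasonal + diel sediment temperature (degC).

    Annual sinusoid peaking in late July (day of year ~207, so the warm
    maximum falls inside May-September) with a small diel cycle.
    """
    doy = index.dayofyear.to_numpy() + index.hour.to_numpy() / 24.0
    hod = index.hour.to_numpy() + index.minute.to_numpy() / 60.0
    seasonal = 15.0 + 12.0 * np.cos(2.0 * np.pi * (doy - 207.0) / 365.25)
    diel = 0.5 * np.sin(2.0 * np.pi * (hod - 10.0) / 24.0)
    return seasonal + diel


def gen_drivers(config: SimConfig) -> pd.DataFrame:
    """Generate a complete 30-min driver table.

    Columns: sed_t, air_t (degC); le, h (W m-2); wind_speed (m s-1);
    wind_dir (deg); u_star (m s-1); par (umol m-2 s-1); water_depth (m);
    p_atm, p_static, dp_static (Pa).  Fully observed, no gaps.
    """
    idx = config.index_30min()
    n = len(idx)
    rng = np.random.default_rng(config.seed)
    ns = config.noise_sd

    doy = idx.dayofyear.to_numpy() + idx.hour.to_numpy() / 24.0
    hod = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0

    sed_t = sediment_temperature(idx) + _ar1(rng, n, ns["sed_t"])
    air_t = (
        12.0
        + 15.0 * np.cos(2.0 * np.pi * (doy - 200.0) / 365.25)
        + 5.0 * np.sin(2.0 * np.pi * (hod - 9.0) / 24.0)
        + _ar1(rng, n, ns["air_t"], phi=0.9)
    )
    sun = np.sin(2.0 * np.pi * (hod - 6.0) / 24.0).clip(min=0.0)
    season_sun = 0.6 + 0.4 * np.cos(2.0 * np.pi * (doy - 172.0) / 365.25)
    le = 120.0 * sun * season_sun + 10.0 + _ar1(rng, n, ns["le"], phi=0.8)
    h = 0.35 * (le - 10.0) - 5.0 + _ar1(rng, n, ns["h"], phi=0.8)
    wind = np.abs(3.0 + _ar1(rng, n, ns["wind"], phi=0.98) * 2.0)
    wind_dir = np.mod(
        200.0 + np.cumsum(rng.normal(0.0, 4.0, n)) if ns["wind"] > 0 else np.full(n, 200.0),
        360.0,
    )
    u_star = (0.03 + 0.035 * wind + _ar1(rng, n, ns["u_star"], phi=0.8)).clip(min=0.01)
    par = 1800.0 * sun * season_sun + np.abs(_ar1(rng, n, ns["par"], phi=0.5)) * sun
    depth = 2.0 + 0.3 * np.cos(2.0 * np.pi * (doy - 120.0) / 365.25) + _ar1(
        rng, n, ns["depth"], phi=0.99
    )
    p_atm = P_ATM_STANDARD + _ar1(rng, n, ns["p_atm"], phi=0.99)
    p_static = p_atm + RHO_WATER * GRAVITY * depth
    dp_static = np.diff(p_static, prepend=p_static[0])

    return pd.DataFrame(
        {
            "sed_t": sed_t,
            "air_t": air_t,
            "le": le,
            "h": h,
            "wind_speed": wind,
            "wind_dir": wind_dir,
            "u_star": u_star,
            "par": par,
            "water_depth": depth,
            "p_atm": p_atm,
            "p_static": p_static,
            "dp_static": dp_static,
        },
        index=idx,
    )


def _exp_response(
    temp: np.ndarray, baseline: float, q10: float, threshold: float
) -> np.ndarray:
    """Exponential temperature response above a threshold, flat below.

    F(T) = baseline * q10**((T - threshold)/10) for T >= threshold, else
    baseline; continuous at the threshold.
    """
    out = np.full_like(temp, baseline, dtype=float)
    above = temp >= threshold
    out[above] = baseline * np.power(q10, (temp[above] - threshold) / 10.0)
    return out


def gen_true_flux(drivers: pd.DataFrame, config: SimConfig) -> TruthBundle:
    """True 30-min flux per stratum from the drivers.

    The shallow stratum carries the exponential temperature response plus
    the Gaussian-in-time spring-burst pulse; the deep stratum carries its
    own (lower-Q10, lower-threshold) response and no burst.
    """
    if drivers.isna().any().any():
        raise ValueError("drivers must be complete")
    idx = drivers.index
    temp = drivers["sed_t"].to_numpy()

    shallow = _exp_response(
        temp, config.baseline_flux, config.q10_true, config.threshold_temp_true
    )
    deep = config.deep_scale * _exp_response(
        temp, config.baseline_flux, config.q10_true_deep, config.threshold_temp_deep
    )

    burst = np.zeros(len(idx))
    if config.burst_amplitude != 0.0:
        b0, b1 = (pd.Timestamp(t, tz="UTC") for t in config.burst_window)
        center = b0 + (b1 - b0) / 2
        sigma_s = max((b1 - b0).total_seconds() / 6.0, 1.0)
        dt_s = (idx - center).total_seconds().to_numpy()
        pulse = config.burst_amplitude * np.exp(-0.5 * (dt_s / sigma_s) ** 2)
        inside = (idx >= b0) & (idx <= b1 + pd.Timedelta("1D"))
        burst[inside] = pulse[inside]
    shallow = shallow + burst

    sh_eb = config.ebullitive_share_shallow
    dp_eb = config.ebullitive_share_deep
    flux = pd.DataFrame(
        {
            "shallow_total": shallow,
            "shallow_ebullitive": sh_eb * shallow,
            "shallow_diffusive": (1.0 - sh_eb) * shallow,
            "deep_total": deep,
            "deep_ebullitive": dp_eb * deep,
            "deep_diffusive": (1.0 - dp_eb) * deep,
        },
        index=idx,
    )
    return TruthBundle(drivers=drivers, flux=flux, config=config)


def _gap_mask(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    """Boolean mask of missing records: mixture of blocks and singletons.

    The achieved missing count equals round(gap_fraction * n) exactly.
    """
    target = int(round(config.gap_fraction * n))
    mask = np.zeros(n, dtype=bool)
    block_quota = int(round(config.block_gap_share * target))
    # multi-record outages: half-day to three-day blocks on the 30-min grid
    placed, attempts = 0, 0
    while placed < block_quota and attempts < 10 * n:
        length = int(rng.integers(24, 145))
        start = int(rng.integers(0, max(n - length, 1)))
        newly = ~mask[start : start + length]
        take = min(int(newly.sum()), block_quota - placed)
        if take > 0:
            sel = np.flatnonzero(newly)[:take]
            mask[start + sel] = True
            placed += take
        attempts += 1
    # singleton dropouts fill the remainder exactly
    remaining = target - int(mask.sum())
    if remaining > 0:
        candidates = np.flatnonzero(~mask)
        mask[rng.choice(candidates, size=remaining, replace=False)] = True
    return mask


def gen_ec_observations(truth: TruthBundle, config: SimConfig) -> pd.DataFrame:
    """EC-style 30-min observations of the shallow-stratum total flux.

    Columns: fch4 (NaN at gaps), random_error, qc_level, u_star, wind_dir,
    site.  Noise is Gaussian and independent per record; the per-record
    random-error field mimics a ~15 % flux-proportional error magnitude.
    """
    if config.gap_fraction >= 1.0:
        raise ValueError("gap_fraction = 1 leaves nothing to train on")
    rng = np.random.default_rng(config.seed + 1)
    total = truth.flux["shallow_total"]
    n = len(total)
    noise = rng.normal(0.0, config.noise_sd["ec"], n) if config.noise_sd["ec"] else 0.0
    obs = total.to_numpy() + noise
    mask = _gap_mask(rng, n, config)
    fch4 = obs.copy()
    fch4[mask] = np.nan

    qc = rng.choice([0, 1, 2], size=n, p=[0.7, 0.25, 0.05])
    out = pd.DataFrame(
        {
            "fch4": fch4,
            "random_error": np.maximum(0.15 * np.abs(obs), 0.1),
            "qc_level": qc,
            "u_star": truth.drivers["u_star"],
            "wind_dir": truth.drivers["wind_dir"],
            "site": "S2",
        },
        index=total.index,
    )
    out.attrs["truth"] = total
    out.attrs["gap_mask"] = mask
    return out


@dataclass
class TrapSimulation:
    """A simulated active-funnel-trap record plus its generating truth."""

    voltage: pd.Series  # V on the 5-min grid
    true_flux: pd.Series  # mg CH4 m-2 h-1 per 5-min interval
    injected_volume: pd.Series  # m3 of gas added per 5-min interval
    purge_times: pd.DatetimeIndex

    @property
    def total_injected_volume(self) -> float:
        return float(self.injected_volume.sum())


def gen_trap_voltage(
    truth: TruthBundle,
    cal,
    config: SimConfig,
    stratum: str = "deep",
) -> TrapSimulation:
    """Simulate the differential-pressure voltage of an active funnel trap.

    Bubble arrivals follow an inhomogeneous Poisson process whose rate
    tracks the true ebullitive flux of ``stratum``; bubble volumes are
    lognormal (strictly positive, right-skewed).  When the accumulated gas
    volume exceeds ``trap_capacity`` the siphon purges (volume resets to
    zero, a large negative voltage step).  The voltage is the inverse of
    the height-calibration map, plus electronic noise.
    """
    if config.trap_capacity <= config.bubble_volume_median:
        raise ValueError("trap capacity must exceed a single bubble volume")
    rng = np.random.default_rng(config.seed + 2)
    idx = config.index_5min()
    n = len(idx)
    dt_h = 5.0 / 60.0

    eb = (
        truth.flux[f"{stratum}_ebullitive"]
        .reindex(idx, method="ffill")
        .bfill()
        .to_numpy()
    )
    mean_eb = eb.mean()
    lam = np.zeros(n) if (config.bubble_rate == 0 or mean_eb <= 0) else (
        config.bubble_rate * dt_h * eb / mean_eb
    )
    counts = rng.poisson(lam)
    total_bubbles = int(counts.sum())
    mu = math.log(config.bubble_volume_median)
    vols = rng.lognormal(mu, config.bubble_volume_sigma, total_bubbles)
    step_vol = np.zeros(n)
    if total_bubbles:
        starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
        nz = counts > 0
        step_vol[nz] = np.add.reduceat(vols, starts[nz])

    trap_vol = np.empty(n)
    purges = []
    v = 0.0
    for i in range(n):
        v += step_vol[i]
        trap_vol[i] = v
        if v > config.trap_capacity:
            # siphon fires after the reading; the drop appears next step
            v = 0.0
            purges.append(i)

    # invert the linear height calibration (heights in cm, diameter in cm)
    d_cm = cal.aft_d * 100.0
    tube_area_cm2 = math.pi * (d_cm / 2.0) ** 2
    height_cm = trap_vol * 1.0e6 / tube_area_cm2
    volt = (height_cm - cal.b) / cal.m
    sd = config.noise_sd["trap_volt"]
    if sd:
        volt = volt + rng.normal(0.0, sd, n)

    true_flux = step_vol * config.bubble_ch4_mg_m3 / (dt_h * cal.a_f)
    return TrapSimulation(
        voltage=pd.Series(volt, index=idx, name="circ_volt"),
        true_flux=pd.Series(true_flux, index=idx, name="true_flux"),
        injected_volume=pd.Series(step_vol, index=idx, name="injected_volume"),
        purge_times=idx[purges],
    )


@dataclass
class ChamberDeployment:
    """A single floating-chamber headspace trace and its generating flux."""

    trace: pd.DataFrame  # columns t_s, ch4_ppm
    geometry: object
    true_flux: float  # mg CH4 m-2 h-1
    spike_index: int | None = None


def gen_chamber_trace(
    true_diffusive_flux: float,
    geom,
    config: SimConfig,
    duration_s: float = 240.0,
    dt_s: float = 5.0,
    chi0: float = 2.0,
    mode: str = "linear",
    k: float = 0.005,
    spike_at: int | None = None,
) -> ChamberDeployment:
    """Simulate a chamber headspace CH4 mixing-ratio trace (ppm, 5-s step).

    ``linear`` mode rises at the mixing-ratio rate implied by the flux and
    chamber geometry; ``saturating`` mode follows an exponential approach
    to equilibrium whose t = 0 slope matches that rate.  ``spike_at``
    injects an ebullition step for spike-detector tests.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    from resflux.chamber_flux import rate_from_flux

    rng = np.random.default_rng(config.seed + 3)
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    slope = rate_from_flux(true_diffusive_flux, geom)  # ppm s-1
    if mode == "linear":
        chi = chi0 + slope * t
    elif mode == "saturating":
        chi_eq = chi0 + slope / k
        chi = chi_eq + (chi0 - chi_eq) * np.exp(-k * t)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    sd = config.noise_sd["chamber_ppm"]
    if sd:
        chi = chi + rng.normal(0.0, sd, len(t))
    if spike_at is not None:
        step = 20.0 * max(slope, sd, 1e-3) * dt_s
        chi[spike_at:] += step
    trace = pd.DataFrame({"t_s": t, "ch4_ppm": chi})
    return ChamberDeployment(
        trace=trace, geometry=geom, true_flux=true_diffusive_flux, spike_index=spike_at
    )


def gen_survey(
    truth: TruthBundle, config: SimConfig, survey_date: str | pd.Timestamp
) -> pd.DataFrame:
    """Per-site survey table for one survey date.

    Site depths are drawn from a linear hypsographic (depth-to-area)
    curve, i.e. uniformly over (0, max_depth); inclusion weights are
    post-stratified so that the weighted mean is the area-weighted lake
    mean.  Per-site fluxes are the stratum truth (daily mean on the
    survey date) plus independent site noise.
    """
    rng = np.random.default_rng(
        config.seed + 4 + int(pd.Timestamp(survey_date).dayofyear)
    )
    ts = pd.Timestamp(survey_date)
    date = (ts.tz_localize("UTC") if ts.tz is None else ts.tz_convert("UTC")).normalize()
    n = config.n_sites
    depths = rng.uniform(0.2, config.max_depth, n)
    is_deep = depths >= config.depth_cutoff

    day = truth.flux.loc[truth.flux.index.normalize() == date]
    if day.empty:
        raise ValueError(f"survey date {survey_date} outside simulation span")
    means = day.mean()
    sd = config.noise_sd["survey"]

    diff = np.where(
        is_deep, means["deep_diffusive"], means["shallow_diffusive"]
    ) + (rng.normal(0.0, sd, n) if sd else 0.0)
    eb = np.where(
        is_deep, means["deep_ebullitive"], means["shallow_ebullitive"]
    ) + (rng.normal(0.0, sd, n) if sd else 0.0)
    diff = np.clip(diff, 0.0, None)
    eb = np.clip(eb, 0.0, None)

    # post-stratified inclusion weights from the linear hypsographic curve
    frac_shallow = config.depth_cutoff / config.max_depth
    n_sh = int((~is_deep).sum())
    n_dp = int(is_deep.sum())
    weights = np.where(
        is_deep,
        (1.0 - frac_shallow) / max(n_dp, 1),
        frac_shallow / max(n_sh, 1),
    )

    return pd.DataFrame(
        {
            "site": [f"U-{i + 1:02d}" for i in range(n)],
            "depth_m": depths,
            "diffusive": diff,
            "ebullitive": eb,
            "total": diff + eb,
            "weight": weights,
            "is_deep": is_deep,
            "date": date,
        }
    )


def write_streams(outdir, truth: TruthBundle, ec: pd.DataFrame, config: SimConfig) -> None:
    """Write streams as plain CSV with ISO-8601 UTC timestamps + schema."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth.drivers.to_csv(out / "drivers.csv", index_label="timestamp", date_format="%Y-%m-%dT%H:%M:%SZ")
    truth.flux.to_csv(out / "true_flux.csv", index_label="timestamp", date_format="%Y-%m-%dT%H:%M:%SZ")
    ec.to_csv(out / "ec_observations.csv", index_label="timestamp", date_format="%Y-%m-%dT%H:%M:%SZ")
    cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()}
    cfg["noise_sd"] = dict(config.noise_sd)
    with open(out / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    schema = """# Stream schemas

All timestamps are ISO-8601 UTC on regular grids.

drivers.csv (30-min): sed_t, air_t [degC]; le, h [W m-2]; wind_speed
[m s-1]; wind_dir [deg]; u_star [m s-1]; par [umol m-2 s-1];
water_depth [m]; p_atm, p_static, dp_static [Pa].

true_flux.csv (30-min): per-stratum true CH4 flux components
[mg CH4 m-2 h-1]; *_total = *_diffusive + *_ebullitive.

ec_observations.csv (30-min): fch4 [mg CH4 m-2 h-1, blank at gaps];
random_error [mg CH4 m-2 h-1]; qc_level [0-2]; u_star [m s-1];
wind_dir [deg]; site.
"""
    (out / "schema.md").write_text(schema)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
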