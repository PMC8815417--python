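"""Funnel-trap ebullition reduction with propagated uncertainty.

Active funnel traps (AFTs) log the differential-pressure voltage of a gas
collection tube on a 5-min grid; an auto-purging siphon empties the tube
whenever it fills.  The reduction chain is: voltage -> gas volume via a
linear height calibration, a 60-min (12-point) moving average to suppress
sensor noise, removal of siphon-purge steps, rolling-bin conversion of
volume increments to an ebullitive CH4 flux using the bubble-gas CH4
concentration, and root-sum-square error propagation through the whole
chain.  Passive funnel traps (PFTs) use the same flux equation with a
directly measured volume over an overnight deployment.

Heights from the calibration map are in cm and tubing diameters in m
(converted internally), so volumes come out in m^3; fluxes are reported
in mg CH4 m^-2 h^-1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TrapCalibration",
    "BubbleGas",
    "ALLOWED_BIN_WIDTHS",
    "voltage_to_volume",
    "smooth_volume",
    "filter_purges",
    "default_purge_threshold",
    "ebullitive_flux",
    "propagate_trap_error",
    "pft_flux",
    "daily_and_cumulative",
    "reduce_trap_series",
]

#: rolling-bin widths supported for flux computation
ALLOWED_BIN_WIDTHS = ("30min", "1h", "2h", "6h", "12h", "24h", "48h")


@dataclass(frozen=True)
class TrapCalibration:
    """Sensor-specific calibration and error terms for one funnel trap.

    ``m`` and ``b`` map voltage to gas-column height in cm
    (height = circ_volt * m + b); ``aft_d`` is the collection-tube
    diameter in m.  Error terms follow the trap error model: slope error
    ``dm``, offset-voltage mean/SD ``v_zero``/``dv_zero`` (V), electronic
    noise ``dv_out`` (V), and a fixed dead volume (m^3) lost to fittings
    at each siphon purge.
    """

    m: float = 31.0  # cm per volt (study mean slope)
    b: float = -15.81  # cm
    aft_d: float = 0.10  # m, funnel-tubing diameter
    a_f: float = 0.3  # m^2, funnel cross-sectional area
    dm: float = 0.31  # cm per volt, slope error
    v_zero: float = 0.51  # V, offset-voltage mean
    dv_zero: float = 0.071  # V, offset-voltage SD
    dv_out: float = 0.003  # V, electronic noise
    dead_volume: float = 2.0e-6  # m^3 per purge (2 mL)

    def __post_init__(self) -> None:
        if self.m <= 0 or self.aft_d <= 0 or self.a_f <= 0:
            raise ValueError("m, aft_d and a_f must be positive")
        for name in ("dm", "dv_zero", "dv_out", "dead_volume"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def tube_area_m2(self) -> float:
        return math.pi * (self.aft_d / 2.0) ** 2

    def volume_error_m3(self, circ_volt: float | np.ndarray = 0.0) -> np.ndarray:
        """Per-reading volume error (m^3) from slope, offset and noise.

        Height-error components — circ_volt * dm (slope), m * dv_zero
        (offset) and m * dv_out (electronic) — combine in quadrature and
        scale by the tube cross-section.
        """
        h_err_cm = np.sqrt(
            (np.asarray(circ_volt, dtype=float) * self.dm) ** 2
            + (self.m * self.dv_zero) ** 2
            + (self.m * self.dv_out) ** 2
        )
        return h_err_cm / 100.0 * self.tube_area_m2


@dataclass(frozen=True)
class BubbleGas:
    """CH4 content of the trapped bubble gas (mg CH4 per m^3 of gas)."""

    ch4_conc: float = 4.0e5
    ch4_conc_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.ch4_conc < 0 or self.ch4_conc_sd < 0:
            raise ValueError("concentration and its SD must be >= 0")


def voltage_to_volume(
    series: pd.Series, cal: TrapCalibration
) -> tuple[pd.Series, pd.Series]:
    """Convert sensor voltage to trapped gas volume (m^3).

    volume = (circ_volt * m + b) [cm] * pi * (d/2)^2, with the tube
    diameter converted to cm so the product is cm^3 (then m^3).  Returns
    the volume series and a boolean mask of negative computed volumes —
    they are flagged, never silently clipped.
    """
    if cal is None:
        raise ValueError("calibration is required")
    height_cm = series.astype(float) * cal.m + cal.b
    d_cm = cal.aft_d * 100.0
    volume = height_cm * math.pi * (d_cm / 2.0) ** 2 * 1.0e-6  # cm^3 -> m^3
    volume.name = "volume_m3"
    negative = volume < 0
    negative.name = "flag_negative"
    return volume, negative


def smooth_volume(volumes: pd.Series, window: int = 12) -> pd.Series:
    """Centered 12-point (60-min on a 5-min grid) moving average.

    Edges use the available points (shrinking window); an all-missing
    window yields a missing value.
    """
    if len(volumes) < window:
        warnings.warn(
            f"series shorter than {window} points; smoothing window shrinks",
            stacklevel=2,
        )
    return volumes.rolling(window, center=True, min_periods=1).mean()


def default_purge_threshold(volumes: pd.Series) -> float:
    """Default purge threshold: 5x the 95th percentile of positive steps.

    Siphon purges are order-of-magnitude larger negative steps than any
    bubble-driven increment.
    """
    steps = volumes.diff().dropna()
    positive = steps[steps > 0]
    if positive.empty:
        return np.inf
    return 5.0 * float(np.percentile(positive, 95))


def filter_purges(
    volumes: pd.Series, threshold: float | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """Remove siphon-purge steps, returning a de-purged cumulative series.

    Negative steps larger in magnitude than ``threshold`` are marked as
    purge events; their increments are excluded (set to zero) so that
    differences of the returned series across a purge reflect only gas
    accumulation.  Returns (clean cumulative volume, purge-event table
    with columns timestamp and magnitude_m3).
    """
    if threshold is None:
        threshold = default_purge_threshold(volumes)
    if threshold <= 0:
        raise ValueError("purge threshold must be positive")
    steps = volumes.diff()
    is_purge = (steps < -threshold).to_numpy()
    # smoothing smears a siphon drop across the averaging window, so
    # contiguous flagged steps belong to one physical purge event
    flagged = np.flatnonzero(is_purge)
    starts, magnitudes = [], []
    run_start = None
    run_sum = 0.0
    prev = -10
    for i in flagged:
        if i != prev + 1:
            if run_start is not None:
                starts.append(run_start)
                magnitudes.append(run_sum)
            run_start, run_sum = i, 0.0
        run_sum += -float(steps.iloc[i])
        prev = i
    if run_start is not None:
        starts.append(run_start)
        magnitudes.append(run_sum)
    events = pd.DataFrame(
        {
            "timestamp": volumes.index[starts],
            "magnitude_m3": magnitudes,
        }
    )
    # excluded purge increments are replaced by the local accumulation
    # rate (mean of nearby non-purge steps) so that gas arriving while
    # the siphon fires is not silently dropped from the mass balance
    clean_steps = steps.where(~is_purge)
    local_rate = clean_steps.rolling(49, center=True, min_periods=1).mean()
    clean_steps = clean_steps.fillna(local_rate.fillna(0.0))
    if len(clean_steps):
        clean_steps.iloc[0] = 0.0
    clean = clean_steps.cumsum()
    if len(volumes):
        clean = clean + volumes.iloc[0]
    clean.name = "cumulative_volume_m3"
    return clean, events


def ebullitive_flux(
    volumes: pd.Series,
    gas: BubbleGas,
    cal: TrapCalibration,
    bin_width: str = "2h",
) -> pd.Series:
    """Rolling-bin ebullitive flux (mg CH4 m^-2 h^-1).

    flux = delta(volume) * [CH4] / (elapsed_hours * A_F) over right-closed
    rolling bins labeled by their end time.  ``volumes`` must be the
    purge-corrected cumulative series.
    """
    if bin_width not in ALLOWED_BIN_WIDTHS:
        raise ValueError(f"bin_width must be one of {ALLOWED_BIN_WIDTHS}")
    delta = pd.Timedelta(bin_width)
    hours = delta.total_seconds() / 3600.0
    if hours <= 0:
        raise ValueError("zero elapsed time")
    earlier = volumes.reindex(volumes.index - delta)
    earlier.index = volumes.index
    dv = volumes - earlier
    flux = dv * gas.ch4_conc / (hours * cal.a_f)
    flux.name = f"flux_{bin_width}"
    return flux


def propagate_trap_error(
    flux: pd.Series,
    cal: TrapCalibration,
    gas: BubbleGas,
    bin_width: str = "2h",
    purge_count: int = 0,
    smoothing_window: int = 12,
) -> tuple[pd.Series, float]:
    """Per-flux errors and the cumulative-emission error.

    The per-flux error treats a bin as the difference of two smoothed
    volume readings, each carrying the offset-voltage SD and the
    electronic noise propagated through the height calibration (noise is
    reduced by the moving average), plus the relative slope and
    bubble-gas concentration errors scaling with the flux itself.

    For the cumulative error the terms separate by correlation
    structure: electronic noise is independent per bin and accumulates
    over non-overlapping bins; slope and concentration errors are fully
    correlated (relative errors on the total); the offset re-zeroing
    uncertainty and the fixed dead volume enter once per siphon purge
    cycle.  All parts combine in quadrature.

    Returns (per-record flux error, mg CH4 m^-2 h^-1; cumulative error,
    g CH4 m^-2).
    """
    hours = pd.Timedelta(bin_width).total_seconds() / 3600.0
    area = cal.tube_area_m2
    off_vol = cal.m * cal.dv_zero / 100.0 * area  # m^3, offset SD
    noise_vol = cal.m * cal.dv_out / 100.0 * area / math.sqrt(smoothing_window)
    reading_err = math.sqrt(off_vol**2 + noise_vol**2)
    base_err = math.sqrt(2.0) * reading_err * gas.ch4_conc / (hours * cal.a_f)
    rel_conc = gas.ch4_conc_sd / gas.ch4_conc if gas.ch4_conc > 0 else 0.0
    rel = math.sqrt((cal.dm / cal.m) ** 2 + rel_conc**2)
    flux_err = np.sqrt(base_err**2 + (flux.abs() * rel) ** 2)
    flux_err = pd.Series(flux_err, index=flux.index, name="flux_error")

    step = max(int(round(hours / _grid_hours(flux))), 1)
    independent = flux.iloc[::step].dropna()
    total_mg_m2 = float(independent.sum()) * hours
    rand_mg = math.sqrt(len(independent)) * (
        math.sqrt(2.0) * noise_vol * gas.ch4_conc / cal.a_f
    )
    sys_mg = abs(total_mg_m2) * rel
    per_cycle_mg = math.sqrt(
        (off_vol * gas.ch4_conc / cal.a_f) ** 2
        + (cal.dead_volume * gas.ch4_conc / cal.a_f) ** 2
    )
    cyc_mg = math.sqrt(max(purge_count, 0)) * per_cycle_mg
    cumulative_err_g = math.sqrt(rand_mg**2 + sys_mg**2 + cyc_mg**2) / 1000.0
    return flux_err, cumulative_err_g


def _grid_hours(series: pd.Series) -> float:
    if len(series) < 2:
        return 1.0
    return (series.index[1] - series.index[0]).total_seconds() / 3600.0


def pft_flux(
    collected_volume: float,
    gas: BubbleGas,
    deployment_hours: float,
    a_f: float = 0.3,
) -> float:
    """Single passive-trap flux from a directly measured gas volume.

    flux = volume * [CH4] / (deployment * A_F), mg CH4 m^-2 h^-1.
    """
    if deployment_hours <= 0:
        raise ValueError("deployment duration must be positive")
    if collected_volume <= 0:
        if collected_volume < 0:
            warnings.warn("negative collected volume treated as zero flux", stacklevel=2)
        return 0.0
    return collected_volume * gas.ch4_conc / (deployment_hours * a_f)


def daily_and_cumulative(
    flux: pd.Series,
    flux_error: pd.Series | None = None,
    max_gap: str = "6h",
) -> tuple[pd.DataFrame, float, float]:
    """Daily means and the cumulative emission (g CH4 m^-2).

    Gaps shorter than ``max_gap`` are linearly interpolated; longer gaps
    stay missing and are reported via the daily table's ``n_obs`` column.
    Daily mean flux x 24 h summed gives the cumulative emission; the
    cumulative error is the quadrature sum of daily errors.

    Returns (daily table with columns flux, error, n_obs; cumulative
    g CH4 m^-2; cumulative error g CH4 m^-2).
    """
    limit = max(int(pd.Timedelta(max_gap) / (flux.index[1] - flux.index[0])), 1)
    filled = flux.interpolate(method="time", limit=limit, limit_area="inside")
    daily = filled.resample("1D").mean()
    n_obs = filled.resample("1D").count()
    if flux_error is not None:
        derr = flux_error.resample("1D").mean().reindex(daily.index)
    else:
        derr = pd.Series(0.0, index=daily.index)
    table = pd.DataFrame({"flux": daily, "error": derr, "n_obs": n_obs})
    valid = daily.dropna()
    cumulative = float(valid.sum()) * 24.0 / 1000.0  # mg -> g
    cum_err = math.sqrt(float((derr.reindex(valid.index) * 24.0 / 1000.0).pow(2).sum()))
    return table, cumulative, cum_err


def reduce_trap_series(
    voltage: pd.Series,
    cal: TrapCalibration,
    gas: BubbleGas,
    bin_width: str = "2h",
    purge_threshold: float | None = None,
) -> dict:
    """Full AFT reduction: voltage -> smoothed volume -> purge-filtered
    cumulative volume -> rolling-bin flux with propagated errors.

    Returns a dict with keys volume, negative_mask, clean_volume, purges,
    flux, flux_error, cumulative_error.
    """
    volume, negative = voltage_to_volume(voltage, cal)
    smoothed = smooth_volume(volume)
    clean, purges = filter_purges(smoothed, purge_threshold)
    flux = ebullitive_flux(clean, gas, cal, bin_width)
    flux_err, cum_err = propagate_trap_error(
        flux, cal, gas, bin_width, purge_count=len(purges)
    )
    return {
        "volume": volume,
        "negative_mask": negative,
        "clean_volume": clean,
        "purges": purges,
        "flux": flux,
        "flux_error": flux_err,
        "cumulative_error": cum_err,
    }
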