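"""Quality control and driver preparation for eddy-covariance records.

Filters follow the tower deployment history: at the near-shore site (S1)
periods with wind from the land sector — the closed, north-wrapping
interval [195 deg, 33 deg] — are rejected; at the open-water site (S2) a
friction-velocity threshold (u* < 0.07 m s^-1 rejected, boundary
retained) screens poorly developed turbulence.  Records failing the
integrated stationarity/turbulence quality scale (level 2) are rejected
at both sites.  The module also aggregates per-record random flux errors
by season, fills driver gaps (weather-station substitution with linear
cross-calibration, or mean-diurnal-course averaging), and derives the
static pressure driver (atmospheric + hydrostatic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from resflux.constants import GRAVITY, RHO_WATER

__all__ = [
    "FilterConfig",
    "apply_qc",
    "season_of",
    "aggregate_random_error",
    "fill_driver_gaps",
    "mean_diurnal_course",
    "derive_static_pressure",
]

#: drivers filled by weather-station substitution (cross-calibrated)
STATION_FILLED = ("sed_t", "air_t", "wind_speed", "wind_dir", "p_atm")
#: drivers filled by the mean diurnal course
MDC_FILLED = ("le", "h", "u_star")


@dataclass(frozen=True)
class FilterConfig:
    """EC rejection rules.

    ``wind_sector_reject`` is a (from_deg, to_deg) interval that may wrap
    through north; endpoints are rejected (closed interval).  ``u_star_min``
    rejects records with u* strictly below it.  ``qc_max`` is the highest
    acceptable quality level on the 0-2 integrated scale.
    """

    wind_sector_reject: tuple[float, float] = (195.0, 33.0)
    u_star_min: float = 0.07
    qc_max: int = 1

    def __post_init__(self) -> None:
        lo, hi = self.wind_sector_reject
        if not (0 <= lo < 360 and 0 <= hi < 360):
            raise ValueError("wind sector bounds must be in [0, 360)")

    def in_reject_sector(self, wind_dir: np.ndarray) -> np.ndarray:
        lo, hi = self.wind_sector_reject
        wd = np.mod(np.asarray(wind_dir, dtype=float), 360.0)
        if lo <= hi:
            return (wd >= lo) & (wd <= hi)
        return (wd >= lo) | (wd <= hi)  # wraps through north


def apply_qc(
    records: pd.DataFrame, config: FilterConfig, site: str
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the site-specific filters; flux of rejected records -> NaN.

    Returns the filtered table and a rejection ledger with per-cause
    counts (a record rejected for quality is not double-counted under the
    site-specific cause).  Filtering is idempotent.
    """
    if site not in ("S1", "S2"):
        raise ValueError(f"unknown site {site!r}; expected 'S1' or 'S2'")
    out = records.copy()
    observed = out["fch4"].notna().to_numpy()

    bad_qc = (out["qc_level"].to_numpy() > config.qc_max) & observed
    remaining = observed & ~bad_qc
    if site == "S1":
        bad_site = config.in_reject_sector(out["wind_dir"].to_numpy()) & remaining
        site_cause = "wind_sector"
    else:
        bad_site = (out["u_star"].to_numpy() < config.u_star_min) & remaining
        site_cause = "u_star"

    out.loc[bad_qc | bad_site, "fch4"] = np.nan
    ledger = {
        "qc_level": int(bad_qc.sum()),
        site_cause: int(bad_site.sum()),
        "total_rejected": int((bad_qc | bad_site).sum()),
    }
    return out, ledger


def season_of(index: pd.DatetimeIndex) -> pd.Series:
    """Season labels: winter (Nov-Mar), summer (May-Sep), shoulder (Apr, Oct)."""
    month = index.month
    labels = np.where(
        np.isin(month, [11, 12, 1, 2, 3]),
        "winter",
        np.where(np.isin(month, [5, 6, 7, 8, 9]), "summer", "shoulder"),
    )
    return pd.Series(labels, index=index, name="season")


def aggregate_random_error(records: pd.DataFrame) -> pd.DataFrame:
    """Seasonal summary of per-record random flux errors.

    Returns, per season: mean error, SD of error, mean flux, and the
    error as a percentage of the mean flux.  Seasons with no accepted
    records are absent from the table.
    """
    obs = records.dropna(subset=["fch4"])
    if "random_error" not in obs or obs.empty:
        raise ValueError("records must carry a populated random_error column")
    groups = obs.groupby(season_of(obs.index).to_numpy())
    summary = groups.agg(
        mean_error=("random_error", "mean"),
        sd_error=("random_error", "std"),
        mean_flux=("fch4", "mean"),
        n=("fch4", "size"),
    )
    summary["pct_of_mean_flux"] = 100.0 * summary["mean_error"] / summary["mean_flux"].abs()
    return summary


def mean_diurnal_course(
    series: pd.Series,
    window_days: int = 7,
    max_window_days: int = 28,
    min_donors: int = 3,
) -> pd.Series:
    """Fill gaps with the mean of same-time-of-day values nearby in time.

    For each missing half-hour, averages valid values at the same time of
    day within +/- ``window_days``; the window doubles until at least
    ``min_donors`` donors exist or ``max_window_days`` is reached.  Gaps
    with no donors after maximal widening remain missing.
    """
    out = series.copy()
    missing = out.index[out.isna()]
    if missing.empty:
        return out
    valid = series.dropna()
    # group donor values by time of day for fast lookup
    tod = valid.index.hour * 60 + valid.index.minute
    by_tod: dict[int, pd.Series] = {
        key: grp for key, grp in valid.groupby(tod)
    }
    for ts in missing:
        key = ts.hour * 60 + ts.minute
        donors_all = by_tod.get(key)
        if donors_all is None:
            continue
        window = window_days
        while True:
            lo, hi = ts - pd.Timedelta(days=window), ts + pd.Timedelta(days=window)
            donors = donors_all.loc[(donors_all.index >= lo) & (donors_all.index <= hi)]
            if len(donors) >= min_donors or window >= max_window_days:
                break
            window = min(window * 2, max_window_days)
        if len(donors) > 0:
            out.loc[ts] = float(donors.mean())
    return out


def _cross_calibrate(tower: pd.Series, station: pd.Series) -> pd.Series:
    """Linear map station -> tower fitted on the overlap, applied everywhere."""
    overlap = pd.concat({"t": tower, "s": station}, axis=1).dropna()
    if len(overlap) < 2 or overlap["s"].std() == 0:
        return station
    slope, intercept = np.polyfit(overlap["s"], overlap["t"], 1)
    return station * slope + intercept


def fill_driver_gaps(
    drivers: pd.DataFrame, station: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Produce a complete driver table.

    Meteorological drivers with a weather-station analogue are filled by
    station substitution after linear cross-calibration on the overlap;
    LE, H and u* are filled by the mean diurnal course.  Any column not
    covered by either rule falls back to time interpolation.  Returns the
    filled table and a ledger of remaining missing values per column.
    """
    out = drivers.copy()
    for col in out.columns:
        if not out[col].isna().any():
            continue
        if station is not None and col in STATION_FILLED and col in station.columns:
            calibrated = _cross_calibrate(out[col], station[col].reindex(out.index))
            out[col] = out[col].fillna(calibrated)
        elif col in MDC_FILLED:
            out[col] = mean_diurnal_course(out[col])
        if out[col].isna().any():
            out[col] = out[col].interpolate(method="time", limit_direction="both")
    remaining = {c: int(out[c].isna().sum()) for c in out.columns if out[c].isna().any()}
    return out, remaining


def derive_static_pressure(
    air_pressure: pd.Series, water_depth: pd.Series
) -> pd.DataFrame:
    """Static pressure (Pa) over the sediment and its 30-min change.

    P_static = P_atm + rho_w * g * depth with rho_w = 1000 kg m^-3.
    """
    if (water_depth < 0).any():
        raise ValueError("water depth must be non-negative")
    p_static = air_pressure + RHO_WATER * GRAVITY * water_depth
    dp = p_static.diff().fillna(0.0)
    return pd.DataFrame({"p_static": p_static, "dp_static": dp})
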