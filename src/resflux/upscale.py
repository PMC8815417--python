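"""Whole-reservoir upscaling of methane emissions.

Three estimators of whole-lake emission are provided:

* **survey-only** — the inclusion-weighted mean of per-site survey
  fluxes, extended in time by the survey-to-survey interpolation rule
  (first-survey value back to 1 May, last value forward to 15 October,
  zero in between winters);
* **trap + chamber** — continuous single-site records summed daily
  (handled upstream, in the trap and chamber modules);
* **hybrid** — the EC record characterizes the shallow stratum and the
  continuously monitored deep-site trap record, scaled by the reservoir
  ratio (RR, deep sentinel site over the deep survey-site mean), covers
  the deep stratum; stratum cumulative emissions are area-weighted to a
  whole-lake areal total and mass.

Uncertainties of independent components combine in quadrature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReservoirGeometry",
    "survey_mean",
    "reservoir_ratio",
    "rr_interpolate",
    "hybrid_cumulative",
    "survey_upscale_annual",
    "combine_uncertainty",
    "cumulative_from_daily",
]


@dataclass(frozen=True)
class ReservoirGeometry:
    """Stratified surface areas (km^2) and the depth cut between strata."""

    area_total: float = 2.4
    area_shallow: float = 0.8
    area_deep: float = 1.6
    depth_cutoff: float = 3.0  # m

    def __post_init__(self) -> None:
        if abs(self.area_shallow + self.area_deep - self.area_total) > 1e-9:
            raise ValueError("area_shallow + area_deep must equal area_total")


def survey_mean(table: pd.DataFrame) -> tuple[float, float]:
    """Inclusion-weighted whole-lake mean flux and its 95 % CI half-width.

    Sites with missing fluxes are dropped (reported via a warning).  The
    CI uses the weighted-SRS variance of the weighted mean — a stated
    simplification of the spatially balanced design's local-neighborhood
    variance estimator.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 survey sites")
    t = table.dropna(subset=["total", "weight"])
    if len(t) < len(table):
        warnings.warn(f"dropped {len(table) - len(t)} site(s) with missing fluxes", stacklevel=2)
    w = t["weight"].to_numpy(dtype=float)
    if (w <= 0).any():
        raise ValueError("inclusion weights must be positive")
    w = w / w.sum()
    f = t["total"].to_numpy(dtype=float)
    mean = float(w @ f)
    var_mean = float((w**2 * (f - mean) ** 2).sum())
    return mean, 1.96 * math.sqrt(var_mean)


def reservoir_ratio(deep_aft_total: float, deep_sites: pd.DataFrame) -> float:
    """RR = sentinel deep-site total flux / mean of other deep sites' totals."""
    sites = deep_sites[deep_sites["is_deep"]] if "is_deep" in deep_sites else deep_sites
    if sites.empty:
        raise ValueError("need at least one deep survey site")
    site_mean = float(sites["total"].mean())
    if site_mean == 0:
        raise ValueError("deep-site mean flux is zero; RR undefined")
    return deep_aft_total / site_mean


def rr_interpolate(
    anchors: list[tuple[pd.Timestamp, float]],
    span: tuple[pd.Timestamp, pd.Timestamp],
) -> pd.Series:
    """Daily RR series: linear between anchors, constant outside.

    The first survey's RR applies to all earlier days, the last survey's
    to all later days.
    """
    if not anchors:
        raise ValueError("need at least one RR anchor")
    dates = pd.DatetimeIndex([pd.Timestamp(d) for d, _ in anchors])
    values = [v for _, v in anchors]
    series = pd.Series(values, index=dates).sort_index()
    days = pd.date_range(pd.Timestamp(span[0]).normalize(), pd.Timestamp(span[1]).normalize(), freq="1D")
    daily = series.reindex(series.index.union(days))
    daily = daily.interpolate(method="time").ffill().bfill()
    out = daily.reindex(days)
    out.name = "rr"
    return out


def cumulative_from_daily(daily_flux: pd.Series) -> float:
    """Cumulative areal emission (g CH4 m^-2) from daily mean fluxes
    in mg CH4 m^-2 h^-1."""
    return float(daily_flux.dropna().sum()) * 24.0 / 1000.0


def hybrid_cumulative(
    ec_daily: pd.Series,
    deep_aft_daily: pd.Series,
    rr: pd.Series,
    geom: ReservoirGeometry,
    errors: dict[str, float] | None = None,
) -> dict[str, float]:
    """Hybrid whole-reservoir emission estimate.

    The deep-stratum daily flux is the deep sentinel-site flux scaled to
    the deep-stratum mean level by the reservoir ratio — the sentinel
    series divided by RR(t), since RR is sentinel over stratum mean;
    stratum cumulatives are weighted by stratum area fractions:

        areal = (A_shallow * C_shallow + A_deep * C_deep) / A_total
        mass  = areal * A_total  (Mg CH4 for areas in km^2)

    ``errors`` may carry cumulative-scale uncertainties (g CH4 m^-2) for
    the "ec", "aft" and "survey" components, combined in quadrature.
    Returns a dict with cum_shallow, cum_deep, areal_g_m2, mass_mg
    (megagrams), error_g_m2, error_mg.
    """
    if not ec_daily.index.equals(deep_aft_daily.index):
        common = ec_daily.index.intersection(deep_aft_daily.index)
        if common.empty:
            raise ValueError("EC and deep AFT daily series do not overlap")
        ec_daily = ec_daily.reindex(common)
        deep_aft_daily = deep_aft_daily.reindex(common)
    rr_aligned = rr.reindex(ec_daily.index).ffill().bfill()
    if (rr_aligned <= 0).any():
        raise ValueError("reservoir ratio must be positive to scale the sentinel series")
    deep_daily = deep_aft_daily / rr_aligned

    cum_sh = cumulative_from_daily(ec_daily)
    cum_dp = cumulative_from_daily(deep_daily)
    areal = (geom.area_shallow * cum_sh + geom.area_deep * cum_dp) / geom.area_total
    mass = areal * geom.area_total  # g m^-2 * km^2 = Mg (1e6 m^2 / 1e6 g)

    err_areal = 0.0
    if errors:
        # stratum errors scale by their area fraction before combining
        parts = []
        if "ec" in errors:
            parts.append(errors["ec"] * geom.area_shallow / geom.area_total)
        for key in ("aft", "survey"):
            if key in errors:
                parts.append(errors[key] * geom.area_deep / geom.area_total)
        err_areal = combine_uncertainty(parts)
    return {
        "cum_shallow": cum_sh,
        "cum_deep": cum_dp,
        "areal_g_m2": areal,
        "mass_mg": mass,
        "error_g_m2": err_areal,
        "error_mg": err_areal * geom.area_total,
    }


def survey_upscale_annual(
    surveys: list[tuple[pd.Timestamp, float]],
    year: int,
) -> tuple[float, pd.Series]:
    """Annual cumulative areal emission from a year's surveys.

    The first survey's flux applies to every day from 1 May to the first
    survey; fluxes interpolate linearly between surveys; the last
    survey's flux applies through 15 October; zero outside 1 May-15 Oct.
    Returns (cumulative g CH4 m^-2, the daily flux series for the year).
    """
    if not surveys:
        raise ValueError("need at least one survey")
    dates = pd.DatetimeIndex([pd.Timestamp(d).normalize() for d, _ in surveys])
    vals = [v for _, v in surveys]
    start, stop = pd.Timestamp(f"{year}-05-01"), pd.Timestamp(f"{year}-10-15")
    if dates.tz is not None:
        start, stop = start.tz_localize(dates.tz), stop.tz_localize(dates.tz)
    if (dates < start).any() or (dates > stop).any():
        warnings.warn("survey outside the 1 May-15 Oct window still honored", stacklevel=2)
    anchors = pd.Series(vals, index=dates).sort_index()

    days_all = pd.date_range(
        min(start, dates.min()), max(stop, dates.max()), freq="1D"
    )
    daily = anchors.reindex(anchors.index.union(days_all))
    daily = daily.interpolate(method="time").ffill().bfill()
    daily = daily.reindex(days_all)
    # zero-emission assumption outside the open-water accounting window
    daily[(daily.index < start) | (daily.index > stop)] = 0.0

    year_days = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="1D", tz=dates.tz)
    out = daily.reindex(year_days, fill_value=0.0)
    out.name = "survey_daily_flux"
    return cumulative_from_daily(out), out


def combine_uncertainty(errors) -> float:
    """Quadrature combination of independent error magnitudes."""
    arr = np.asarray(list(errors), dtype=float)
    if arr.size == 0:
        return 0.0
    if (arr < 0).any():
        raise ValueError("error magnitudes must be non-negative")
    return float(np.sqrt((arr**2).sum()))
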