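"""Temperature-response, breakpoint, diurnal and limnological statistics.

* ecological Q10 — the ecosystem-scale multiplicative change in flux per
  10 degC of warming: ecoQ10 = 10^(10 b), with b the OLS slope of
  log10(flux) against temperature (only this regression direction makes
  10^(10 b) the 10-degree factor);
* 2-D Kolmogorov-Smirnov breakpoint — the temperature at which the
  joint (temperature, flux) sample deviates most from independence,
  found by the four-quadrant construction over candidate origins at the
  observed points, with a permutation p-value;
* a daily diurnal-pattern classifier (day/night median contrast with a
  smoothness requirement);
* the size-productivity model relating total CH4 emission to
  chlorophyll-a;
* dissolved CH4 from headspace equilibration via the temperature-specific
  Bunsen solubility coefficient;
* Brunt-Vaisala buoyancy frequency from a temperature-depth profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from resflux.constants import (
    GRAVITY,
    MOLAR_MASS_C,
    MOLAR_MASS_CH4,
    MOLAR_VOLUME_STP,
    P_ATM_STANDARD,
    R_GAS,
)

__all__ = [
    "EcoQ10Result",
    "BreakpointResult",
    "SizeProductivityModel",
    "eco_q10",
    "breakpoint_2dks",
    "diurnal_classifier",
    "size_productivity_flux",
    "bunsen_ch4",
    "dissolved_ch4",
    "water_density",
    "buoyancy_frequency",
]


@dataclass
class EcoQ10Result:
    b: float  # slope of log10(flux) vs temperature, per degC
    eco_q10: float  # 10 ** (10 b)
    r2: float
    n_used: int
    n_excluded: int  # nonpositive fluxes dropped before the log


def eco_q10(
    temps, fluxes, daily_means: bool = True, min_pairs: int = 10
) -> EcoQ10Result:
    """Ecological Q10 from paired temperature/flux records.

    Nonpositive fluxes are excluded (counted in the result).  When both
    inputs are time-indexed and ``daily_means`` is set, pairs are
    aggregated to daily means first — temperature response at the
    ecosystem scale is a slow signal and 30-min scatter only dilutes it.
    """
    t = pd.Series(temps).astype(float)
    f = pd.Series(fluxes).astype(float)
    if daily_means and isinstance(t.index, pd.DatetimeIndex):
        t = t.resample("1D").mean()
        f = f.resample("1D").mean()
    pair = pd.concat({"t": t, "f": f}, axis=1).dropna()
    n_excluded = int((pair["f"] <= 0).sum())
    pair = pair[pair["f"] > 0]
    if len(pair) == 0:
        raise ValueError("all fluxes are nonpositive; cannot fit a log response")
    if len(pair) < min_pairs:
        raise ValueError(f"need >= {min_pairs} positive pairs, got {len(pair)}")
    res = stats.linregress(pair["t"], np.log10(pair["f"]))
    return EcoQ10Result(
        b=float(res.slope),
        eco_q10=float(10.0 ** (10.0 * res.slope)),
        r2=float(res.rvalue**2),
        n_used=len(pair),
        n_excluded=n_excluded,
    )


@dataclass
class BreakpointResult:
    threshold_temp: float  # temperature coordinate of the maximizing origin
    d_statistic: float
    p_value: float
    n_permutations: int


def _d2ks(xle: np.ndarray, yle: np.ndarray) -> tuple[float, int]:
    """Max four-quadrant disagreement over candidate origins.

    ``xle[i, j]`` is True when x_j <= x_i (likewise yle).  For each
    origin the empirical quadrant fraction is compared with the product
    of the marginals; D is the largest absolute difference over the four
    quadrants and all origins.  Returns (D, index of maximizing origin).
    """
    fx = xle.mean(axis=1)
    fy = yle.mean(axis=1)
    q11 = (xle & yle).mean(axis=1)
    # remaining quadrants follow from the marginals
    d11 = np.abs(q11 - fx * fy)
    d12 = np.abs((fx - q11) - fx * (1 - fy))
    d21 = np.abs((fy - q11) - (1 - fx) * fy)
    d22 = np.abs((1 - fx - fy + q11) - (1 - fx) * (1 - fy))
    per_origin = np.maximum(np.maximum(d11, d12), np.maximum(d21, d22))
    i = int(np.argmax(per_origin))
    return float(per_origin[i]), i


def breakpoint_2dks(
    temps, fluxes, n_permutations: int = 999, seed: int = 0
) -> BreakpointResult:
    """2-D Kolmogorov-Smirnov breakpoint between temperature and flux.

    The statistic D measures the largest deviation of the joint sample
    from the independence hypothesis over the four quadrants anchored at
    each observed point; the temperature of the maximizing anchor is the
    reported threshold.  The p-value permutes flux against temperature.
    """
    x = np.asarray(temps, dtype=float)
    y = np.asarray(fluxes, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 20:
        raise ValueError("need >= 20 pairs for the 2DKS test")
    if np.unique(x).size == 1:
        raise ValueError("all temperatures tie; no breakpoint is identifiable")

    xle = x[None, :] <= x[:, None]
    yle = y[None, :] <= y[:, None]
    d_obs, i_max = _d2ks(xle, yle)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        d_perm, _ = _d2ks(xle, yle[np.ix_(perm, perm)])
        if d_perm >= d_obs:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return BreakpointResult(
        threshold_temp=float(x[i_max]),
        d_statistic=d_obs,
        p_value=float(p),
        n_permutations=n_permutations,
    )


def diurnal_classifier(
    fluxes: pd.Series,
    is_day: pd.Series,
    min_records: int = 8,
    contrast: float = 0.5,
    min_autocorr: float = 0.5,
) -> str:
    """Classify one day's 30-min fluxes as strong-day/strong-night/none.

    Requires at least ``min_records`` non-gap-filled records in each of
    the day and night classes ("insufficient" otherwise).  A strong
    pattern needs (a) a day/night median contrast above ``contrast``
    relative to the smaller median magnitude and (b) smoothness,
    quantified as lag-1 autocorrelation >= ``min_autocorr``.  When the
    smaller median is zero the contrast is undefined; the fallback
    compares the absolute median difference with the day's median
    absolute deviation.
    """
    f = fluxes.dropna()
    day = f[is_day.reindex(f.index).fillna(False).astype(bool)]
    night = f[~is_day.reindex(f.index).fillna(False).astype(bool)]
    if len(day) < min_records or len(night) < min_records:
        return "insufficient"
    md, mn = float(day.median()), float(night.median())
    series = f.sort_index().to_numpy()
    if len(series) > 2 and np.std(series) > 0:
        ac1 = float(np.corrcoef(series[:-1], series[1:])[0, 1])
    else:
        ac1 = 0.0

    smaller = min(abs(md), abs(mn))
    if smaller == 0.0:
        mad = float(stats.median_abs_deviation(f, scale="normal"))
        strong = abs(md - mn) > mad and ac1 >= min_autocorr
    else:
        strong = abs(md - mn) / smaller > contrast and ac1 >= min_autocorr
    if not strong:
        return "none"
    return "strong-day" if md > mn else "strong-night"


@dataclass(frozen=True)
class SizeProductivityModel:
    """Published coefficients of the chlorophyll-a emission model:
    log10(total_CH4 + 1) = c1 * log10(chl_a) + c2."""

    c1: float = 0.778
    c2: float = 0.940


def size_productivity_flux(
    chl_a: float, model: SizeProductivityModel | None = None
) -> dict[str, float]:
    """Total CH4 emission predicted from chlorophyll-a (ug L^-1).

    Returns both the native mg C m^-2 d^-1 value and its conversion to
    mg CH4 m^-2 h^-1 (x M_CH4/M_C, / 24 h).
    """
    if chl_a <= 0:
        raise ValueError("chlorophyll-a must be positive")
    m = model or SizeProductivityModel()
    total_c = 10.0 ** (m.c1 * math.log10(chl_a) + m.c2) - 1.0
    return {
        "mg_c_m2_d": total_c,
        "mg_ch4_m2_h": total_c * (MOLAR_MASS_CH4 / MOLAR_MASS_C) / 24.0,
    }


def bunsen_ch4(temp_c: float) -> float:
    """Bunsen solubility coefficient of CH4 in fresh water.

    Volume of gas (STP) absorbed per volume of water at 1 atm partial
    pressure; standard three-term fit in T(K)/100, zero salinity, valid
    roughly 0-40 degC.
    """
    if not 0.0 <= temp_c <= 40.0:
        raise ValueError("temperature outside the solubility fit range (0-40 degC)")
    t = (temp_c + 273.15) / 100.0
    return math.exp(-67.1962 + 99.1624 / t + 27.9015 * math.log(t))


def dissolved_ch4(
    headspace_ppm: float,
    water_temp_c: float,
    v_headspace_ml: float = 25.0,
    v_water_ml: float = 115.0,
    pressure_pa: float = P_ATM_STANDARD,
) -> float:
    """Original dissolved CH4 (umol L^-1) from headspace equilibration.

    A water sample is equilibrated against a CH4-free headspace; the
    original concentration is the equilibrium headspace moles (ideal
    gas) plus the moles remaining dissolved (Bunsen coefficient), per
    volume of water.
    """
    if v_headspace_ml <= 0 or v_water_ml <= 0:
        raise ValueError("volumes must be positive")
    t_k = water_temp_c + 273.15
    p_ch4 = headspace_ppm * 1e-6 * pressure_pa  # Pa
    v_hs = v_headspace_ml * 1e-6  # m^3
    v_w = v_water_ml * 1e-3  # L
    n_headspace = p_ch4 * v_hs / (R_GAS * t_k)  # mol
    beta = bunsen_ch4(water_temp_c)
    # dissolved equilibrium conc: beta * partial pressure (atm) / molar volume
    c_aq = beta * (p_ch4 / P_ATM_STANDARD) / MOLAR_VOLUME_STP  # mol per L water
    n_dissolved = c_aq * v_w
    return (n_headspace + n_dissolved) / v_w * 1e6  # umol L^-1


def water_density(temp_c: np.ndarray | float) -> np.ndarray | float:
    """Fresh-water density (kg m^-3), standard polynomial, 0-40 degC."""
    t = np.asarray(temp_c, dtype=float)
    rho = 1000.0 * (
        1.0 - (t + 288.9414) / (508929.2 * (t + 68.12963)) * (t - 3.9863) ** 2
    )
    return rho if rho.ndim else float(rho)


def buoyancy_frequency(
    depths_m, temps_c
) -> tuple[pd.DataFrame, float]:
    """Brunt-Vaisala N^2 profile (s^-2) and the maximum N (s^-1).

    N^2 = (g / rho) * d(rho)/dz with depth increasing downward; centered
    differences on the (strictly increasing) depth grid.  Negative N^2
    (statically unstable layers) is floored at zero for the N maximum.
    """
    z = np.asarray(depths_m, dtype=float)
    t = np.asarray(temps_c, dtype=float)
    if z.size < 3:
        raise ValueError("need at least 3 depths")
    if not np.all(np.diff(z) > 0):
        raise ValueError("depths must be strictly increasing")
    rho = water_density(t)
    drho_dz = np.gradient(rho, z)
    n2 = GRAVITY / rho * drho_dz
    n_max = float(np.sqrt(np.clip(n2, 0.0, None).max()))
    profile = pd.DataFrame({"depth_m": z, "temp_c": t, "n2_s2": n2})
    return profile, n_max
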