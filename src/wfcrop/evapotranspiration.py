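"""Daily reference evapotranspiration (FAO-56 Penman-Monteith).

Computes ET0 of the standard grass reference surface from daily weather:
ET0 = [0.408 Δ (Rn − G) + γ (900/(T+273)) u2 (es − ea)] / [Δ + γ (1 + 0.34 u2)]
with soil heat flux G = 0 at the daily step, albedo 0.23, and the standard
longwave term from temperature, humidity and relative shortwave. Wind is
assumed measured at 2 m. Results are clamped at zero (no negative ET0).
"""

from __future__ import annotations

import numpy as np

ALBEDO = 0.23
STEFAN_BOLTZMANN = 4.903e-9  # MJ K-4 m-2 day-1
SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1

__all__ = [
    "saturation_vapour_pressure",
    "extraterrestrial_radiation",
    "net_radiation",
    "reference_et0",
    "et0_series",
]


def saturation_vapour_pressure(temp_c):
    """Saturation vapour pressure (kPa) at air temperature (degC)."""
    temp_c = np.asarray(temp_c, dtype=float)
    return 0.6108 * np.exp(17.27 * temp_c / (temp_c + 237.3))


def extraterrestrial_radiation(latitude_deg, day_of_year):
    """Daily extraterrestrial radiation Ra (MJ m-2 day-1)."""
    lat = np.deg2rad(np.asarray(latitude_deg, dtype=float))
    doy = np.asarray(day_of_year, dtype=float)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi / 365.0 * doy)
    decl = 0.409 * np.sin(2.0 * np.pi / 365.0 * doy - 1.39)
    x = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    ws = np.arccos(x)  # sunset hour angle
    ra = (24.0 * 60.0 / np.pi) * SOLAR_CONSTANT * dr * (
        ws * np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.sin(ws)
    )
    return np.maximum(ra, 0.0)


def net_radiation(srad, tmax, tmin, ea, latitude_deg, elevation_m, day_of_year):
    """Net radiation at the grass surface (MJ m-2 day-1).

    Shortwave: (1 − albedo)·Rs. Longwave: Stefan-Boltzmann on the mean of
    Tmax^4/Tmin^4 with humidity and cloudiness corrections; relative
    shortwave Rs/Rso is clipped to [0.33, 1].
    """
    srad = np.asarray(srad, dtype=float)
    ra = extraterrestrial_radiation(latitude_deg, day_of_year)
    rso = (0.75 + 2e-5 * np.asarray(elevation_m, dtype=float)) * ra
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(rso > 0, srad / np.where(rso > 0, rso, 1.0), 0.33)
    rel = np.clip(rel, 0.33, 1.0)
    rns = (1.0 - ALBEDO) * srad
    tmax_k = np.asarray(tmax, dtype=float) + 273.16
    tmin_k = np.asarray(tmin, dtype=float) + 273.16
    rnl = (
        STEFAN_BOLTZMANN
        * (tmax_k**4 + tmin_k**4)
        / 2.0
        * (0.34 - 0.14 * np.sqrt(np.maximum(ea, 0.0)))
        * (1.35 * rel - 0.35)
    )
    return rns - rnl


def reference_et0(
    tmax,
    tmin,
    rh,
    wind,
    srad,
    latitude_deg=45.0,
    elevation_m=0.0,
    day_of_year=180,
    net_radiation_override=None,
):
    """FAO-56 Penman-Monteith daily reference ET0 (mm/day).

    Parameters
    ----------
    tmax, tmin : degC, with tmin <= tmax
    rh : mean relative humidity, % in [0, 100]
    wind : wind speed at 2 m, m/s
    srad : shortwave radiation, MJ m-2 day-1
    net_radiation_override : optional Rn (MJ m-2 day-1) bypassing the internal
        radiation budget; useful when Rn is observed.

    Returns ET0 >= 0. Vectorises over numpy arrays.
    """
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    rh = np.asarray(rh, dtype=float)
    wind = np.asarray(wind, dtype=float)
    srad = np.asarray(srad, dtype=float)
    if np.any(tmin > tmax + 1e-12):
        raise ValueError("tmin must not exceed tmax")
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity must lie in [0, 100] %")
    if np.any(wind < 0) or np.any(srad < 0):
        raise ValueError("wind and shortwave radiation must be non-negative")

    tmean = (tmax + tmin) / 2.0
    es_mean = saturation_vapour_pressure(tmean)
    delta = 4098.0 * es_mean / (tmean + 237.3) ** 2
    pressure = 101.3 * ((293.0 - 0.0065 * np.asarray(elevation_m, float)) / 293.0) ** 5.26
    gamma = 0.000665 * pressure
    es = (saturation_vapour_pressure(tmax) + saturation_vapour_pressure(tmin)) / 2.0
    ea = rh / 100.0 * es
    if net_radiation_override is not None:
        rn = np.asarray(net_radiation_override, dtype=float)
    else:
        rn = net_radiation(srad, tmax, tmin, ea, latitude_deg, elevation_m, day_of_year)
    num = 0.408 * delta * rn + gamma * (900.0 / (tmean + 273.0)) * wind * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * wind)
    et0 = num / den
    return np.maximum(et0, 0.0)


def et0_series(weather, latitude_deg, elevation_m=0.0):
    """ET0 for a whole WeatherSeries (see synthetic_world), aligned 1:1.

    Returns a float array of mm/day, same length as the forcing.
    """
    return reference_et0(
        weather.tmax,
        weather.tmin,
        weather.rh,
        weather.wind,
        weather.srad,
        latitude_deg=latitude_deg,
        elevation_m=elevation_m,
        day_of_year=weather.day_of_year,
    )
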