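"""Reference crop evapotranspiration from temperature and latitude.

ET0 is computed with the Hargreaves-Samani temperature method, the standard
choice when only air temperature is observed. Extraterrestrial radiation Ra
follows the FAO-56 closed form (solar declination, inverse relative
Earth-Sun distance, sunset hour angle).
"""

from __future__ import annotations

import numpy as np

SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1
#: Conversion from radiation (MJ m-2 day-1) to evaporation equivalent (mm/day)
RADIATION_TO_MM = 0.408
HARGREAVES_COEF = 0.0023
HARGREAVES_TEMP_OFFSET = 17.8  # degC


def extraterrestrial_radiation(latitude, day_of_year):
    """FAO-56 extraterrestrial radiation Ra (MJ m-2 day-1).

    Parameters
    ----------
    latitude : array_like
        Degrees, in [-90, 90].
    day_of_year : array_like
        1..366 (day 366 is treated as day 365; the difference is
        negligible at seasonal scale).

    The sunset-hour-angle argument is clamped to [-1, 1], so polar night
    yields Ra = 0 and polar day the full 24-hour integral.
    """
    lat = np.asarray(latitude, dtype=float)
    doy = np.asarray(day_of_year)
    if np.any((lat < -90) | (lat > 90)):
        raise ValueError("latitude must lie in [-90, 90] degrees")
    if np.any((doy < 1) | (doy > 366)):
        raise ValueError("day_of_year must lie in 1..366")
    j = np.minimum(doy, 365).astype(float)

    phi = np.deg2rad(lat)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * j / 365.0)
    delta = 0.409 * np.sin(2.0 * np.pi * j / 365.0 - 1.39)
    cos_ws = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    ws = np.arccos(cos_ws)
    ra = (
        (24.0 * 60.0 / np.pi)
        * SOLAR_CONSTANT
        * dr
        * (ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws))
    )
    return np.maximum(ra, 0.0)


def hargreaves_et0(tmin, tmean, tmax, ra):
    """Daily reference evapotranspiration (mm/day) by Hargreaves-Samani.

    ET0 = 0.0023 * 0.408 * Ra * (Tmean + 17.8) * sqrt(Tmax - Tmin),
    floored at zero (very cold conditions would otherwise go negative).
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    tmean = np.asarray(tmean, dtype=float)
    if np.any(tmin > tmax + 1e-9):
        raise ValueError("tmin must not exceed tmax")
    trange = np.maximum(tmax - tmin, 0.0)
    et0 = (
        HARGREAVES_COEF
        * RADIATION_TO_MM
        * np.asarray(ra, dtype=float)
        * (tmean + HARGREAVES_TEMP_OFFSET)
        * np.sqrt(trange)
    )
    return np.maximum(et0, 0.0)


def season_et0(climate) -> np.ndarray:
    """ET0 for every district, year and season day of a ClimateSeries.

    Returns an array of shape (n_districts, n_years, n_season_days).
    """
    n_d, n_y, n_s = climate.tmean.shape
    doy = climate.season_start_doy + np.arange(n_s)
    doy = np.where(doy > 365, doy - 365, doy)  # wrap, if a season crosses Dec 31
    ra = extraterrestrial_radiation(climate.latitude[:, None], doy[None, :])
    return hargreaves_et0(
        climate.tmin, climate.tmean, climate.tmax, ra[:, None, :]
    )
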