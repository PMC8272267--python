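"""Local solar time, sunrise/sunset, daylight and roosting-hour flags.

Self-contained NOAA solar-position approximation (fractional-year Fourier
series for declination and the equation of time; official sunrise/sunset
zenith of 90.833 degrees).  All timestamps are naive UTC; "local" means mean
solar time, i.e. UTC shifted by lon/15 hours — tracks cross civil time
zones, so civil clocks are never used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

OFFICIAL_ZENITH_DEG = 90.833  # sun centre 0.833 deg below horizon: rise/set

POLAR_DAY = "polar_day"
POLAR_NIGHT = "polar_night"


@dataclass(frozen=True)
class SolarContext:
    """Roosting window in local solar hours (default 17:00-08:00)."""

    roost_start_local: float = 17.0
    roost_end_local: float = 8.0

    def __post_init__(self) -> None:
        for h in (self.roost_start_local, self.roost_end_local):
            if not 0 <= h < 24:
                raise ValueError("roost hours must lie in [0, 24)")


def local_solar_time(timestamp_utc, lon):
    """Mean solar time: UTC shifted by lon/15 hours."""
    return pd.Timestamp(timestamp_utc) + pd.Timedelta(hours=float(lon) / 15.0)


def local_solar_hour(times_utc, lons) -> np.ndarray:
    """Vectorized fractional local solar hour-of-day in [0, 24)."""
    t = np.asarray(times_utc, dtype="datetime64[s]").astype(float)
    hours_utc = (t / 3600.0) % 24.0
    return (hours_utc + np.asarray(lons, dtype=float) / 15.0) % 24.0


def _fractional_year_rad(times_utc) -> np.ndarray:
    t = pd.DatetimeIndex(np.atleast_1d(np.asarray(times_utc, dtype="datetime64[s]")))
    doy = t.dayofyear.to_numpy(float)
    hour = t.hour.to_numpy(float) + t.minute.to_numpy(float) / 60.0
    return 2.0 * np.pi / 365.0 * (doy - 1.0 + (hour - 12.0) / 24.0)


def equation_of_time_min(times_utc) -> np.ndarray:
    g = _fractional_year_rad(times_utc)
    return 229.18 * (0.000075 + 0.001868 * np.cos(g) - 0.032077 * np.sin(g)
                     - 0.014615 * np.cos(2 * g) - 0.040849 * np.sin(2 * g))


def solar_declination_rad(times_utc) -> np.ndarray:
    g = _fractional_year_rad(times_utc)
    return (0.006918 - 0.399912 * np.cos(g) + 0.070257 * np.sin(g)
            - 0.006758 * np.cos(2 * g) + 0.000907 * np.sin(2 * g)
            - 0.002697 * np.cos(3 * g) + 0.00148 * np.sin(3 * g))


def solar_zenith_deg(times_utc, lats, lons) -> np.ndarray:
    """Solar zenith angle in degrees at given UTC instants and positions."""
    t = np.atleast_1d(np.asarray(times_utc, dtype="datetime64[s]"))
    lats = np.broadcast_to(np.asarray(lats, dtype=float), t.shape)
    lons = np.broadcast_to(np.asarray(lons, dtype=float), t.shape)
    eqt = equation_of_time_min(t)
    decl = solar_declination_rad(t)
    minutes_utc = (t.astype(float)) / 60.0 % 1440.0
    tst = minutes_utc + eqt + 4.0 * lons  # true solar time, minutes
    ha = np.radians(tst / 4.0 - 180.0)
    lat_r = np.radians(lats)
    cos_z = (np.sin(lat_r) * np.sin(decl)
             + np.cos(lat_r) * np.cos(decl) * np.cos(ha))
    return np.degrees(np.arccos(np.clip(cos_z, -1.0, 1.0)))


def sunrise_sunset(lat, lon, date):
    """Sunrise and sunset as UTC Timestamps for the given date and position.

    Returns ``(sunrise_utc, sunset_utc)``, or the string flag
    ``"polar_day"`` / ``"polar_night"`` when the sun never sets / rises.
    """
    day = pd.Timestamp(date).normalize()
    noon = day + pd.Timedelta(hours=12)
    decl = float(solar_declination_rad(np.datetime64(noon, "s"))[0])
    eqt = float(equation_of_time_min(np.datetime64(noon, "s"))[0])
    lat_r = np.radians(float(lat))
    cos_ha = (np.cos(np.radians(OFFICIAL_ZENITH_DEG))
              / (np.cos(lat_r) * np.cos(decl))
              - np.tan(lat_r) * np.tan(decl))
    if cos_ha < -1.0:
        return POLAR_DAY
    if cos_ha > 1.0:
        return POLAR_NIGHT
    ha_deg = np.degrees(np.arccos(cos_ha))
    sunrise_min = 720.0 - 4.0 * (float(lon) + ha_deg) - eqt
    sunset_min = 720.0 - 4.0 * (float(lon) - ha_deg) - eqt
    return (day + pd.Timedelta(minutes=sunrise_min),
            day + pd.Timedelta(minutes=sunset_min))


def is_daylight(timestamp_utc, lat, lon) -> bool:
    """True iff the sun is up (zenith <= 90.833 deg) at this instant/place."""
    z = solar_zenith_deg(np.datetime64(pd.Timestamp(timestamp_utc), "s"), lat, lon)
    return bool(z[0] <= OFFICIAL_ZENITH_DEG)


def daylight_flags(times_utc, lats, lons) -> np.ndarray:
    """Vectorized :func:`is_daylight` for arrays of fixes."""
    z = solar_zenith_deg(times_utc, lats, lons)
    return z <= OFFICIAL_ZENITH_DEG


def is_roost_hours(timestamp_utc, lon, ctx: SolarContext = SolarContext()) -> bool:
    """True iff the local solar hour falls in the roosting window."""
    return bool(roost_flags([np.datetime64(pd.Timestamp(timestamp_utc), "s")],
                            [lon], ctx)[0])


def roost_flags(times_utc, lons, ctx: SolarContext = SolarContext()) -> np.ndarray:
    """Vectorized roosting-hours flag."""
    h = local_solar_hour(times_utc, lons)
    a, b = ctx.roost_start_local, ctx.roost_end_local
    if a <= b:
        return (h >= a) & (h < b)
    return (h >= a) | (h < b)


def next_local_0800_utc(timestamp_utc, lon, hour_local: float = 8.0) -> pd.Timestamp:
    """UTC instant of the next time the local solar clock reads ``hour_local``.

    If the local clock already reads exactly ``hour_local``, that instant is
    returned unchanged.
    """
    t = pd.Timestamp(timestamp_utc)
    local = local_solar_time(t, lon)
    target = local.normalize() + pd.Timedelta(hours=hour_local)
    if target < local:
        target += pd.Timedelta(days=1)
    return target - pd.Timedelta(hours=float(lon) / 15.0)
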