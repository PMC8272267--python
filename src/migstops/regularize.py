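"""Hourly regularization of irregular tracks and per-step speeds."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .track_model import Track

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km on a sphere of radius 6371.0088 km.

    Accepts scalars or numpy arrays (broadcast).
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.minimum(1.0, np.sqrt(a)))


@dataclass
class RegularTrack:
    """Hourly, gap-interpolated trajectory with speeds and provenance flags.

    ``fixes`` columns: ``timestamp`` (top-of-hour UTC), ``lon``, ``lat``,
    any weather covariates, ``interpolated`` (bool: no observation within
    30 min) and ``speed_kmh`` (haversine km to the next fix; NaN on the
    last fix).
    """

    individual_id: str
    population: str
    season: str
    fixes: pd.DataFrame

    def __post_init__(self) -> None:
        ts = self.fixes["timestamp"].to_numpy()
        if len(ts) > 1:
            gaps = np.diff(ts).astype("timedelta64[s]").astype(int)
            if not np.all(gaps == 3600):
                raise ValueError("RegularTrack must be exactly hourly")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def times(self) -> np.ndarray:
        return self.fixes["timestamp"].to_numpy()

    @property
    def lon(self) -> np.ndarray:
        return self.fixes["lon"].to_numpy(float)

    @property
    def lat(self) -> np.ndarray:
        return self.fixes["lat"].to_numpy(float)

    @property
    def speed_kmh(self) -> np.ndarray:
        return self.fixes["speed_kmh"].to_numpy(float)

    @property
    def weather_columns(self) -> list[str]:
        skip = {"timestamp", "lon", "lat", "interpolated", "speed_kmh"}
        return [c for c in self.fixes.columns if c not in skip]

    def index_of(self, when) -> int:
        """Index of the fix at timestamp ``when`` (must be on the grid)."""
        ts = self.times
        i = int(np.searchsorted(ts, np.datetime64(pd.Timestamp(when))))
        if i >= len(ts) or ts[i] != np.datetime64(pd.Timestamp(when)):
            raise KeyError(f"{when} not on the hourly grid of this track")
        return i


def _unwrap_lon(lon: np.ndarray) -> np.ndarray:
    """Unwrap longitudes so interpolation crosses the antimeridian correctly."""
    return np.degrees(np.unwrap(np.radians(lon)))


def _rewrap_lon(lon: np.ndarray) -> np.ndarray:
    out = (np.asarray(lon) + 180.0) % 360.0 - 180.0
    # keep +180 as +180 rather than -180
    out[np.isclose(np.asarray(lon) % 360.0, 180.0)] = 180.0
    return out


def interpolate_hourly(track: Track, season: str = "",
                       flag_tolerance_min: float = 30.0) -> RegularTrack:
    """Linearly interpolate a track to exact top-of-hour fixes.

    Positions (and weather covariates) are linear in time between the
    bracketing observed fixes; longitudes are unwrapped first so paths may
    cross the antimeridian.  A fix is flagged ``interpolated`` when no
    observation lies within ``flag_tolerance_min`` minutes of it.

    Raises a warning and returns an empty track if the input spans < 1 h.
    """
    if track.n_fixes < 2:
        raise ValueError("need at least 2 fixes to interpolate")
    ts = track.fixes["timestamp"]
    t0 = ts.iloc[0].ceil("h")
    t1 = ts.iloc[-1].floor("h")
    if t1 < t0:
        warnings.warn("track spans < 1 h; empty hourly track")
        empty = pd.DataFrame({c: pd.Series(dtype=track.fixes[c].dtype)
                              for c in track.fixes.columns})
        empty["interpolated"] = pd.Series(dtype=bool)
        empty["speed_kmh"] = pd.Series(dtype=float)
        return RegularTrack(track.individual_id, track.population, season, empty)

    grid = pd.date_range(t0, t1, freq="h")
    t_obs = ts.to_numpy().astype("datetime64[s]").astype(float)
    t_new = grid.to_numpy().astype("datetime64[s]").astype(float)

    out = pd.DataFrame({"timestamp": grid})
    out["lon"] = _rewrap_lon(np.interp(t_new, t_obs,
                                       _unwrap_lon(track.fixes["lon"].to_numpy(float))))
    out["lat"] = np.interp(t_new, t_obs, track.fixes["lat"].to_numpy(float))
    for col in track.weather_columns:
        v = track.fixes[col].to_numpy(float)
        finite = np.isfinite(v)
        if finite.sum() >= 2:
            out[col] = np.interp(t_new, t_obs[finite], v[finite],
                                 left=np.nan, right=np.nan)
        else:
            out[col] = np.nan

    nearest = np.minimum.reduce([
        np.abs(t_new[:, None] - t_obs[None, :]).min(axis=1)
    ]) if len(t_obs) < 20000 else np.array(
        [np.abs(t_obs - t).min() for t in t_new])
    out["interpolated"] = nearest > flag_tolerance_min * 60.0
    out["speed_kmh"] = np.nan
    return attach_speeds(RegularTrack(track.individual_id, track.population,
                                      season, out))


def attach_speeds(rt: RegularTrack) -> RegularTrack:
    """Set speed_kmh[i] = haversine distance from fix i to fix i+1 (per 1 h)."""
    lon, lat = rt.lon, rt.lat
    if len(rt) >= 2:
        d = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
        rt.fixes["speed_kmh"] = np.append(d, np.nan)
    else:
        rt.fixes["speed_kmh"] = np.nan
    return rt


def split_on_gaps(track: Track, max_gap_h: float = 24.0) -> list[Track]:
    """Split a raw track wherever consecutive fixes are > max_gap_h apart."""
    ts = track.fixes["timestamp"].to_numpy()
    if len(ts) < 2:
        return [track]
    gaps = np.diff(ts).astype("timedelta64[s]").astype(float) / 3600.0
    cut = np.flatnonzero(gaps > max_gap_h)
    if len(cut) == 0:
        return [track]
    bounds = [0, *(cut + 1), len(ts)]
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a >= 2:
            out.append(Track(track.individual_id, track.population,
                             track.fixes.iloc[a:b].reset_index(drop=True)))
    return out


def regularize_track(track: Track, season: str = "",
                     max_gap_h: float = 24.0) -> list[RegularTrack]:
    """Hourly segments of a track, split at gaps longer than ``max_gap_h``."""
    segments = []
    for piece in split_on_gaps(track, max_gap_h):
        rt = interpolate_hourly(piece, season=season)
        if len(rt) >= 2:
            segments.append(rt)
    return segments
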