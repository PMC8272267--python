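"""Shared fixtures: track builders and the 1 s brute-force FPT oracle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from migstops.regularize import RegularTrack, attach_speeds, haversine_km

KM_PER_DEG = 111.195


def make_regular_track(lon, lat, t0="2015-10-20 00:00:00", individual_id="b0",
                       population="pop", season="fall",
                       weather: dict | None = None) -> RegularTrack:
    """Hourly RegularTrack from coordinate arrays (speeds attached)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    df = pd.DataFrame({
        "timestamp": pd.date_range(t0, periods=len(lon), freq="h"),
        "lon": lon, "lat": lat,
    })
    for name, values in (weather or {}).items():
        df[name] = np.asarray(values, dtype=float)
    df["interpolated"] = False
    df["speed_kmh"] = np.nan
    return attach_speeds(RegularTrack(individual_id, population, season, df))


def track_from_steps(step_km, bearing_deg, lat0=40.0, lon0=-100.0, **kw):
    """Track built from per-hour step lengths (km) and bearings (degrees)."""
    step_km = np.asarray(step_km, dtype=float)
    bearing = np.radians(np.asarray(bearing_deg, dtype=float))
    lat = np.empty(len(step_km) + 1)
    lon = np.empty(len(step_km) + 1)
    lat[0], lon[0] = lat0, lon0
    for i, (s, b) in enumerate(zip(step_km, bearing)):
        lat[i + 1] = lat[i] + s * np.cos(b) / KM_PER_DEG
        lon[i + 1] = lon[i] + s * np.sin(b) / (KM_PER_DEG
                                               * np.cos(np.radians(lat[i])))
    return make_regular_track(lon, lat, **kw)


def two_mode_track(rng: np.random.Generator, n_fast=30, n_stop=20, n_fast2=30,
                   speed=35.0):
    """Directed leg, stationary bout, directed leg — two FPT modes."""
    steps = np.concatenate([
        rng.normal(speed, 3.0, n_fast),
        rng.normal(0.0, 0.01, n_stop),
        rng.normal(speed, 3.0, n_fast2),
    ])
    bearings = np.concatenate([
        rng.normal(180.0, 5.0, n_fast),
        rng.uniform(0, 360, n_stop),
        rng.normal(180.0, 5.0, n_fast2),
    ])
    return track_from_steps(np.abs(steps), bearings)


def random_mixture_track(rng: np.random.Generator, n_fixes: int):
    """Random alternation of directed flight, slow wander and stationarity."""
    steps, bearings = [], []
    heading = rng.uniform(0, 360)
    while len(steps) < n_fixes - 1:
        mode = rng.choice(["fly", "slow", "stop"], p=[0.5, 0.25, 0.25])
        k = int(rng.integers(3, 12))
        if mode == "fly":
            steps.extend(np.abs(rng.normal(35, 8, k)))
            bearings.extend(rng.normal(heading, 8, k))
        elif mode == "slow":
            steps.extend(np.abs(rng.normal(3, 1.5, k)))
            bearings.extend(rng.uniform(0, 360, k))
        else:
            steps.extend(np.abs(rng.normal(0.0, 0.02, k)))
            bearings.extend(rng.uniform(0, 360, k))
    steps = np.array(steps[:n_fixes - 1])
    bearings = np.array(bearings[:n_fixes - 1])
    return track_from_steps(steps, bearings,
                            lat0=float(rng.uniform(25, 50)),
                            lon0=float(rng.uniform(-110, -70)))


# --- brute-force FPT oracle -------------------------------------------------

def sample_path_1s(rt: RegularTrack):
    """Linear-in-lon/lat resample of the whole path at 1 s resolution."""
    n = len(rt)
    lon, lat = rt.lon, rt.lat
    out_lon = np.empty((n - 1) * 3600 + 1)
    out_lat = np.empty_like(out_lon)
    f = np.arange(3600) / 3600.0
    for i in range(n - 1):
        s = slice(i * 3600, (i + 1) * 3600)
        out_lon[s] = lon[i] + f * (lon[i + 1] - lon[i])
        out_lat[s] = lat[i] + f * (lat[i + 1] - lat[i])
    out_lon[-1], out_lat[-1] = lon[-1], lat[-1]
    return out_lon, out_lat


def oracle_fpt(path_lon, path_lat, fix_index: int, radius_m: float,
               chunk: int = 7200) -> float:
    """First passage time (hours) at a fix from the 1 s resampled path.

    Scans outward in chunks for the first sample beyond the radius in each
    direction; NaN when either direction never exits.
    """
    c = fix_index * 3600
    r_km = radius_m / 1000.0
    n = len(path_lon)

    fwd = None
    pos = c
    while pos < n:
        hi = min(n, pos + chunk)
        d = haversine_km(path_lon[pos:hi], path_lat[pos:hi],
                         path_lon[c], path_lat[c])
        beyond = np.flatnonzero(d > r_km)
        if len(beyond):
            fwd = pos + beyond[0]
            break
        pos = hi
    bwd = None
    pos = c
    while pos > 0:
        lo = max(0, pos - chunk)
        d = haversine_km(path_lon[lo:pos], path_lat[lo:pos],
                         path_lon[c], path_lat[c])
        beyond = np.flatnonzero(d > r_km)
        if len(beyond):
            bwd = lo + beyond[-1]
            break
        pos = lo
    if fwd is None or bwd is None:
        return float("nan")
    return (fwd - bwd) / 3600.0


@pytest.fixture(scope="session")
def small_dataset():
    """A 6-individual synthetic dataset shared across pipeline tests."""
    from migstops.synthetic_data import SimConfig, simulate_dataset
    cfg = SimConfig(n_individuals=6, seed=11)
    tracks, migrations, truth, weather = simulate_dataset(cfg, 11)
    return cfg, tracks, migrations, truth, weather
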