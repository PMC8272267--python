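"""Synthetic tracks, weather and ground truth for end-to-end validation.

Generates hourly migratory trajectories with the structure the detector
assumes: diurnal flight (roosting 17:00-08:00 local solar), multi-day
directed legs, stopovers forced by precipitation-front events (2 h to 11 d)
whose onsets fall in flight hours, optional slow foraging bouts, and
per-variable weather series with diurnal cycles, AR(1) noise and
front-coupled ramps.  Every forced bout is recorded as a true stopover, so
detection precision/recall and event-alignment lags can be measured against
known truth.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .track_model import Migration, Track

FLIGHT, ROOST, FRONT, FORAGE = "flight", "roost", "front", "forage"

KM_PER_DEG_LAT = 111.195


@dataclass
class SimConfig:
    n_individuals: int = 20
    n_populations: int = 4
    seasons: tuple[str, ...] = ("spring", "fall")
    # kinematics
    cruise_speed_kmh: float = 40.0
    cruise_speed_sd: float = 6.0
    min_flight_speed_kmh: float = 20.0
    heading_sd_deg: float = 6.0
    gps_jitter_km: float = 0.015
    flight_days_min: int = 5
    flight_days_max: int = 8
    # roosting window, local solar hours
    roost_start_local: float = 17.0
    roost_end_local: float = 8.0
    # stopover process
    front_daily_prob: float = 0.30
    front_min_h: int = 2
    front_max_h: int = 264
    front_onset_local: tuple[int, int] = (9, 14)
    forced_immobility: bool = True
    forage_prob_per_migration: float = 0.15
    forage_min_h: int = 30
    forage_max_h: int = 50
    forage_speed_range_kmh: tuple[float, float] = (2.0, 5.0)
    forage_extent_km: float = 10.0
    # weather
    noise_scale: float = 1.0
    ar1_coef: float = 0.8
    precip_front_amp: float = 0.45
    precip_ramp_tau_h: float = 2.0
    front_suppression: float = 0.15
    # activity coupling for the GLMM ground truth:
    # (intercept, precipitation_fraction, thermal_updraft_velocity, temperature)
    activity_betas: tuple[float, float, float, float] = (-1.7, -3.8, 9.2, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.front_daily_prob <= 1:
            raise ValueError("front_daily_prob must lie in [0, 1]")
        if self.front_min_h < 2:
            raise ValueError("front durations must be >= 2 h")


@dataclass
class TrueStopover:
    individual_id: str
    population: str
    season: str
    start: pd.Timestamp
    end: pd.Timestamp
    cause: str  # "front" | "forage"

    @property
    def duration_h(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0


@dataclass
class SyntheticTruth:
    stopovers: list[TrueStopover]
    front_times: list[tuple[str, str, pd.Timestamp, pd.Timestamp]]
    activity_betas: tuple[float, ...]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "individual_id": s.individual_id, "population": s.population,
            "season": s.season, "start": s.start, "end": s.end,
            "cause": s.cause, "duration_h": s.duration_h,
        } for s in self.stopovers])


@dataclass
class WeatherSeries:
    """Per-migration hourly weather plus the movement plan that shaped it."""

    individual_id: str
    population: str
    season: str
    frame: pd.DataFrame            # timestamp + one column per variable
    states: np.ndarray             # per-hour behavior labels
    fronts: list[tuple[pd.Timestamp, pd.Timestamp]]
    forages: list[tuple[pd.Timestamp, pd.Timestamp]]
    start_lon: float
    start_lat: float
    heading_deg: float
    cruise_kmh: float


_POPULATIONS = ("pop_sw", "pop_cc", "pop_wc", "pop_ss")
_POP_LON = {-110.0: "pop_sw", -100.0: "pop_cc", -117.0: "pop_wc", -62.0: "pop_ss"}


def _population_of(i: int, cfg: SimConfig) -> tuple[str, float]:
    pops = _POPULATIONS[:cfg.n_populations]
    lons = list(_POP_LON)[:cfg.n_populations]
    k = i % len(pops)
    return pops[k], lons[k]


def _plan_states(cfg: SimConfig, rng: np.random.Generator, lon0: float,
                 t0: pd.Timestamp):
    """Hour-by-hour behavior plan until the flight-hour budget is spent."""
    flight_budget = int(rng.integers(cfg.flight_days_min,
                                     cfg.flight_days_max + 1) * 9)
    states: list[str] = []
    fronts: list[tuple[int, int]] = []
    forages: list[tuple[int, int]] = []
    front_until = -1
    forage_until = -1
    planned_today = -1
    max_hours = 24 * 40

    h = 0
    while flight_budget > 0 and h < max_hours:
        t = t0 + pd.Timedelta(hours=h)
        local_h = (t.hour + t.minute / 60.0 + lon0 / 15.0) % 24.0
        day = (t + pd.Timedelta(hours=lon0 / 15.0)).dayofyear

        # schedule (at most) one event per local day, at the morning rollover
        if day != planned_today and h > front_until and h > forage_until:
            planned_today = day
            lo, hi = cfg.front_onset_local
            if rng.random() < cfg.front_daily_prob:
                onset_local = int(rng.integers(lo, hi + 1))
                delta = (onset_local - local_h) % 24.0
                start = h + int(np.ceil(delta))
                log_d = rng.uniform(np.log(cfg.front_min_h),
                                    np.log(cfg.front_max_h))
                dur = int(max(cfg.front_min_h, round(np.exp(log_d))))
                fronts.append((start, start + dur))
                front_until = start + dur
            elif rng.random() < cfg.forage_prob_per_migration:
                onset_local = int(rng.integers(lo, 12 + 1))
                delta = (onset_local - local_h) % 24.0
                start = h + int(np.ceil(delta))
                dur = int(rng.integers(cfg.forage_min_h, cfg.forage_max_h + 1))
                forages.append((start, start + dur))
                forage_until = start + dur

        in_front = any(a <= h < b for a, b in fronts)
        in_forage = any(a <= h < b for a, b in forages)
        a, b = cfg.roost_start_local, cfg.roost_end_local
        in_roost = (local_h >= a) or (local_h < b)
        if in_front:
            states.append(FRONT)
        elif in_forage:
            states.append(FORAGE)
        elif in_roost:
            states.append(ROOST)
        else:
            states.append(FLIGHT)
            flight_budget -= 1
        h += 1

    # trim any scheduled-but-unreached events and clip to the realized span
    n = len(states)
    fronts = [(a, min(b, n)) for a, b in fronts if a < n]
    forages = [(a, min(b, n)) for a, b in forages if a < n]
    return np.array(states), fronts, forages


def _season_start(season: str, year: int, rng: np.random.Generator) -> pd.Timestamp:
    # date windows keep daylength <= ~12 h along the whole route so that
    # ordinary overnight roosts always fail the 25 % daylight filter
    if season == "spring":
        base = pd.Timestamp(f"{year}-02-15 00:00:00")
    else:
        base = pd.Timestamp(f"{year}-10-15 00:00:00")
    return base + pd.Timedelta(days=int(rng.integers(0, 6)))


def simulate_weather(config: SimConfig, seed: int | None = None,
                     ) -> list[WeatherSeries]:
    """Hourly weather (and the movement plan) for every individual/season.

    Each variable is a diurnal sinusoid plus AR(1) noise; during fronts the
    precipitation fraction ramps up with its maximal hourly change exactly
    at front onset, while thermal updraft velocity, shortwave radiation,
    sensible heat flux and boundary height are suppressed and temperature
    dips.
    """
    seed = config.seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    out = []
    for i in range(config.n_individuals):
        pop, lon0 = _population_of(i, config)
        for s_idx, season in enumerate(config.seasons):
            rng = np.random.default_rng(np.random.SeedSequence([seed, i, s_idx]))
            year = 2015
            t0 = _season_start(season, year, rng)
            if season == "spring":
                lat0 = float(rng.uniform(20.0, 26.0))
                heading = float(rng.normal(0.0, 3.0))       # due north
            else:
                lat0 = float(rng.uniform(44.0, 50.0))
                heading = float(rng.normal(180.0, 3.0))     # due south
            lon_start = lon0 + float(rng.uniform(-2.0, 2.0))
            states, fronts_h, forages_h = _plan_states(config, rng, lon_start, t0)
            n = len(states)
            times = pd.date_range(t0, periods=n, freq="h")
            frame = _weather_frame(config, rng, times, lon_start, states,
                                   fronts_h)
            cruise = float(np.clip(rng.normal(config.cruise_speed_kmh,
                                              config.cruise_speed_sd),
                                   config.min_flight_speed_kmh, None))
            out.append(WeatherSeries(
                individual_id=f"bird_{i:02d}", population=pop, season=season,
                frame=frame, states=states,
                fronts=[(times[a], times[b - 1] + pd.Timedelta(hours=1))
                        for a, b in fronts_h],
                forages=[(times[a], times[b - 1] + pd.Timedelta(hours=1))
                         for a, b in forages_h],
                start_lon=lon_start, start_lat=lat0, heading_deg=heading,
                cruise_kmh=cruise))
    return out


def _front_factor(n: int, fronts_h, floor: float = 0.15, tau_on: float = 1.5,
                  tau_off: float = 2.0) -> np.ndarray:
    """Suppression factor in [floor, 1]: decays at onset, recovers after end."""
    f = np.ones(n)
    for a, b in fronts_h:
        for h in range(a, min(b, n)):
            f[h] = min(f[h], max(floor, np.exp(-(h - a + 1) / tau_on)))
        # recovery: approach 1 after the front ends
        for h in range(min(b, n), n):
            target = 1.0 - np.exp(-(h - b + 1) / tau_off)
            if f[h] < target:
                f[h] = max(f[h], target)
            else:
                break
    return f


def _precip_ramp(n: int, fronts_h, amp: float, tau: float) -> np.ndarray:
    """Front precipitation: steepest rise in the first hour of the front."""
    p = np.zeros(n)
    for a, b in fronts_h:
        for h in range(a, min(b, n)):
            p[h] = max(p[h], amp * (1.0 - np.exp(-(h - a + 1) / tau)))
        for h in range(min(b, n), n):
            val = amp * np.exp(-(h - b + 1) / tau)
            if val < 1e-3:
                break
            p[h] = max(p[h], val)
    return p


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    eps = rng.normal(0.0, sd, size=n)
    out = np.empty(n)
    acc = 0.0
    for i in range(n):
        acc = phi * acc + eps[i]
        out[i] = acc
    return out


def _weather_frame(cfg: SimConfig, rng: np.random.Generator,
                   times: pd.DatetimeIndex, lon0: float, states: np.ndarray,
                   fronts_h) -> pd.DataFrame:
    n = len(times)
    local_h = ((times.hour + times.minute / 60.0).to_numpy()
               + lon0 / 15.0) % 24.0
    phi = cfg.ar1_coef
    ns = cfg.noise_scale
    supp = _front_factor(n, fronts_h, floor=cfg.front_suppression)

    # daylight-shaped bump peaking at 13:00 local, zero at night
    bump = np.clip(np.sin(np.pi * (local_h - 7.0) / 12.0), 0.0, None)

    thermal = 0.30 * bump * supp + np.clip(_ar1(rng, n, phi, ns * 0.008), -0.05, None)
    thermal = np.clip(thermal, 0.0, None)
    shortwave = 0.60 * bump * supp + np.clip(_ar1(rng, n, phi, ns * 0.015), -0.1, None)
    shortwave = np.clip(shortwave, 0.0, None)
    sensible = 0.40 * bump * supp + _ar1(rng, n, phi, ns * 0.01)
    boundary = (0.2 + 0.8 * np.clip(np.sin(np.pi * (local_h - 8.0) / 13.0),
                                    0.0, None) * supp
                + _ar1(rng, n, phi, ns * 0.02))
    precip = np.clip(0.04 + _ar1(rng, n, phi, ns * 0.01)
                     + _precip_ramp(n, fronts_h, cfg.precip_front_amp,
                                    cfg.precip_ramp_tau_h), 0.0, 1.0)
    temperature = (0.10 + 0.06 * np.cos(2 * np.pi * (local_h - 14.0) / 24.0)
                   - 0.08 * (1.0 - supp) + _ar1(rng, n, phi, ns * 0.005))
    water = np.clip(0.15 + _ar1(rng, n, phi, ns * 0.01)
                    + _precip_ramp(n, fronts_h, 0.3, 5.0), 0.0, None)
    wind = np.clip(0.3 + _ar1(rng, n, phi, ns * 0.04) + 0.15 * (1.0 - supp), 0.0, None)
    pressure = 1.0 + _ar1(rng, n, 0.97, ns * 0.004) - 0.02 * (1.0 - supp)
    orographic = np.clip(0.1 + _ar1(rng, n, phi, ns * 0.03), 0.0, None)

    return pd.DataFrame({
        "timestamp": times,
        "downward_shortwave_radiation": shortwave,
        "sensible_heat_flux": sensible,
        "thermal_updraft_velocity": thermal,
        "total_atmospheric_water": water,
        "precipitation_fraction": precip,
        "boundary_height": boundary,
        "temperature": temperature,
        "wind_speed": wind,
        "surface_pressure": pressure,
        "orographic_updraft_velocity": orographic,
    })


def simulate_tracks(config: SimConfig, weather: list[WeatherSeries],
                    seed: int | None = None,
                    ) -> tuple[list[Track], list[Migration], SyntheticTruth]:
    """Integrate hourly positions from each movement plan.

    Flight hours: directed correlated walk at cruise speed.  Roost and
    front hours: stationary up to GPS jitter.  Forage hours: slow tortuous
    movement confined to a small area.  Returns one Track per individual
    (both seasons concatenated, weather attached per fix), the migration
    table, and the ground truth.
    """
    seed = config.seed if seed is None else seed
    rng_root = np.random.SeedSequence([seed, 7919])
    per_ind: dict[str, list[pd.DataFrame]] = {}
    pop_of: dict[str, str] = {}
    migrations: list[Migration] = []
    true_stops: list[TrueStopover] = []
    front_times = []

    for w_idx, w in enumerate(weather):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7919, w_idx]))
        n = len(w.states)
        lon = np.empty(n)
        lat = np.empty(n)
        lon[0], lat[0] = w.start_lon, w.start_lat
        heading = w.heading_deg
        forage_center = None
        for h in range(1, n):
            state = w.states[h - 1]  # behavior during [h-1, h)
            if state == FLIGHT:
                step = float(np.clip(rng.normal(w.cruise_kmh,
                                                config.cruise_speed_sd),
                                     config.min_flight_speed_kmh, None))
                brg = np.radians(heading + rng.normal(0.0, config.heading_sd_deg))
                forage_center = None
            elif state == FORAGE:
                if forage_center is None:
                    forage_center = (lon[h - 1], lat[h - 1])
                step = float(rng.uniform(*config.forage_speed_range_kmh))
                brg = rng.uniform(0.0, 2 * np.pi)
                # reflect back toward the bout centre near the boundary
                dlon_c = (lon[h - 1] - forage_center[0]) * KM_PER_DEG_LAT \
                    * np.cos(np.radians(lat[h - 1]))
                dlat_c = (lat[h - 1] - forage_center[1]) * KM_PER_DEG_LAT
                if np.hypot(dlon_c, dlat_c) > config.forage_extent_km * 0.4:
                    brg = np.arctan2(-dlon_c, -dlat_c) + rng.normal(0.0, 0.5)
            else:  # roost or front: stationary (forced immobility)
                if config.forced_immobility or state == ROOST:
                    step = 0.0
                else:
                    step = float(rng.uniform(0.0, 0.8))
                brg = rng.uniform(0.0, 2 * np.pi)
            dlat = step * np.cos(brg) / KM_PER_DEG_LAT
            dlon = step * np.sin(brg) / (KM_PER_DEG_LAT
                                         * np.cos(np.radians(lat[h - 1])))
            lat[h] = lat[h - 1] + dlat
            lon[h] = lon[h - 1] + dlon

        jitter = rng.normal(0.0, config.gps_jitter_km, size=(n, 2))
        lat_obs = lat + jitter[:, 0] / KM_PER_DEG_LAT
        lon_obs = lon + jitter[:, 1] / (KM_PER_DEG_LAT
                                        * np.cos(np.radians(lat)))

        df = w.frame.copy()
        df.insert(1, "lon", lon_obs)
        df.insert(2, "lat", lat_obs)
        per_ind.setdefault(w.individual_id, []).append(df)
        pop_of[w.individual_id] = w.population

        t0 = df["timestamp"].iloc[0]
        t_end = df["timestamp"].iloc[-1] + pd.Timedelta(hours=1)
        migrations.append(Migration(w.individual_id, w.population, w.season,
                                    t0, df["timestamp"].iloc[-1]))
        for a, b in w.fronts:
            front_times.append((w.individual_id, w.season, a, b))
        true_stops.extend(_truth_from_states(w, t0))

    tracks = []
    for ind, frames in per_ind.items():
        fixes = pd.concat(frames, ignore_index=True).sort_values("timestamp")
        tracks.append(Track(ind, pop_of[ind], fixes.reset_index(drop=True)))
    truth = SyntheticTruth(stopovers=true_stops, front_times=front_times,
                           activity_betas=config.activity_betas)
    return tracks, migrations, truth


def _truth_from_states(w: WeatherSeries, t0: pd.Timestamp) -> list[TrueStopover]:
    """True stopovers: maximal non-flight runs containing a forced bout.

    A run's start is the first forced (front/forage) hour; its end is the
    instant flight resumes, so front-then-roost nights extend the stopover
    to the next morning's departure, matching the bird's actual behavior.
    """
    states = w.states
    n = len(states)
    out = []
    i = 0
    while i < n:
        if states[i] == FLIGHT:
            i += 1
            continue
        j = i
        while j + 1 < n and states[j + 1] != FLIGHT:
            j += 1
        run = states[i:j + 1]
        forced = np.flatnonzero((run == FRONT) | (run == FORAGE))
        if len(forced):
            a = i + int(forced[0])
            cause = FRONT if FRONT in run[forced] else FORAGE
            end_h = j + 1  # flight resumes at hour j+1 (or the track ends)
            stop = TrueStopover(
                individual_id=w.individual_id, population=w.population,
                season=w.season,
                start=t0 + pd.Timedelta(hours=a),
                end=t0 + pd.Timedelta(hours=min(end_h, n - 1)),
                cause=cause)
            if stop.duration_h >= 2.0:
                out.append(stop)
        i = j + 1
    return out


def simulate_activity_outcomes(truth: SyntheticTruth,
                               weather: list[WeatherSeries],
                               coupling_betas: tuple[float, ...] | None = None,
                               seed: int = 0) -> pd.DataFrame:
    """Per true stopover, draw hourly Bernoulli activity from mean weather.

    activity_rate = logistic(b0 + b_precip * mean precip + b_thermal *
    mean thermal + b_temp * mean temperature); daytime hours are the
    stopover's non-roost hours.
    """
    from scipy.special import expit

    betas = coupling_betas or truth.activity_betas
    rng = np.random.default_rng(np.random.SeedSequence([seed, 104729]))
    by_key = {(w.individual_id, w.season): w for w in weather}
    rows = []
    for s in truth.stopovers:
        w = by_key[(s.individual_id, s.season)]
        f = w.frame
        m = (f["timestamp"] >= s.start) & (f["timestamp"] <= s.end)
        if not m.any():
            continue
        sub = f.loc[m]
        local_h = ((sub["timestamp"].dt.hour).to_numpy()
                   + w.start_lon / 15.0) % 24.0
        daytime = ~((local_h >= 17.0) | (local_h < 8.0))
        n_day = int(daytime.sum())
        mp = float(sub["precipitation_fraction"].mean())
        mt = float(sub["thermal_updraft_velocity"].mean())
        mtemp = float(sub["temperature"].mean())
        eta = betas[0] + betas[1] * mp + betas[2] * mt + betas[3] * mtemp
        p = float(expit(eta))
        n_act = int(rng.binomial(n_day, p)) if n_day > 0 else 0
        rows.append({
            "individual_id": s.individual_id, "population": s.population,
            "season": s.season, "start": s.start, "end": s.end,
            "n_daytime_h": n_day, "n_active_h": n_act,
            "precipitation_fraction": mp, "thermal_updraft_velocity": mt,
            "temperature": mtemp, "true_rate": p,
        })
    return pd.DataFrame(rows)


def simulate_glmm_dataset(n_stopovers: int = 460, n_individuals: int = 34,
                          n_populations: int = 4,
                          betas: tuple[float, float, float, float]
                          = (-1.7, -3.8, 9.2, 3.0),
                          re_sd: float = 0.079,
                          seed: int = 0) -> pd.DataFrame:
    """Standalone design for the GLMM recovery study (no tracks needed).

    Covariate scales are chosen so the published-magnitude coefficients
    produce activity rates well inside (0, 1).
    """
    from scipy.special import expit

    rng = np.random.default_rng(seed)
    ind = rng.integers(0, n_individuals, size=n_stopovers)
    pop_of_ind = rng.integers(0, n_populations, size=n_individuals)
    pop = pop_of_ind[ind]
    u_pop = rng.normal(0.0, re_sd, size=n_populations)
    u_ind = rng.normal(0.0, re_sd, size=n_individuals)

    precip = np.clip(rng.beta(1.2, 6.0, size=n_stopovers) * 0.8, 0.0, 1.0)
    thermal = np.clip(rng.normal(0.15, 0.07, size=n_stopovers), 0.0, None)
    temp = rng.normal(0.10, 0.08, size=n_stopovers)
    trials = rng.integers(5, 28, size=n_stopovers)

    eta = (betas[0] + betas[1] * precip + betas[2] * thermal + betas[3] * temp
           + u_pop[pop] + u_ind[ind])
    y = rng.binomial(trials, expit(eta))
    return pd.DataFrame({
        "individual_id": [f"i{k:02d}" for k in ind],
        "population": [f"p{k}" for k in pop],
        "n_active_h": y, "n_daytime_h": trials,
        "precipitation_fraction": precip,
        "thermal_updraft_velocity": thermal,
        "temperature": temp,
    })


def thin_track(track: Track, mean_interval_h: float,
               seed: int = 0) -> Track:
    """Random fix thinning to a target mean interval (exercises regularize)."""
    if mean_interval_h < 1.0:
        raise ValueError("mean_interval_h must be >= 1 for an hourly source")
    rng = np.random.default_rng(seed)
    keep = rng.random(len(track.fixes)) < 1.0 / mean_interval_h
    keep[0] = keep[-1] = True
    return Track(track.individual_id, track.population,
                 track.fixes.loc[keep].reset_index(drop=True))


def to_movebank_csv(tracks: list[Track], path) -> None:
    """Write tracks in the Movebank dialect the reader consumes."""
    frames = []
    for t in tracks:
        df = t.fixes.copy()
        df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%d %H:%M:%S.%f") \
            .str[:-3]
        df = df.rename(columns={"lon": "location-long", "lat": "location-lat"})
        df["individual-local-identifier"] = t.individual_id
        df["population"] = t.population
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def migrations_to_csv(migrations: list[Migration], path) -> None:
    pd.DataFrame([{
        "individual_id": m.individual_id, "population": m.population,
        "season": m.season,
        "start": m.start.strftime("%Y-%m-%d %H:%M:%S"),
        "end": m.end.strftime("%Y-%m-%d %H:%M:%S"),
    } for m in migrations]).to_csv(path, index=False)


def simulate_dataset(config: SimConfig | None = None, seed: int | None = None):
    """Weather, tracks, migrations and truth in one call."""
    cfg = config or SimConfig()
    seed = cfg.seed if seed is None else seed
    weather = simulate_weather(cfg, seed)
    tracks, migrations, truth = simulate_tracks(cfg, weather, seed)
    return tracks, migrations, truth, weather
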