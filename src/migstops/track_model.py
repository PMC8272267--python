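"""Data model and I/O for GPS tracks, migration tables, and stopover output.

Tracks are Movebank-dialect CSV: one row per GPS fix with columns
``timestamp``, ``location-long``, ``location-lat`` and
``individual-local-identifier``.  Any additional numeric columns are carried
along as per-fix weather covariates.  All timestamps are naive UTC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical Movebank column names
MOVEBANK_COLUMNS = {
    "timestamp": "timestamp",
    "location-long": "lon",
    "location-lat": "lat",
    "individual-local-identifier": "individual_id",
}

#: optional columns that are metadata rather than weather covariates
META_COLUMNS = {"population", "individual-taxon-canonical-name", "study-name",
                "event-id", "visible", "sensor-type", "tag-local-identifier"}

WEATHER_VARIABLES = (
    "downward_shortwave_radiation",
    "sensible_heat_flux",
    "thermal_updraft_velocity",
    "total_atmospheric_water",
    "precipitation_fraction",
    "boundary_height",
    "temperature",
    "wind_speed",
    "surface_pressure",
    "orographic_updraft_velocity",
)


class TrackFormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass
class Track:
    """Ordered geographic fixes for one individual.

    ``fixes`` is a DataFrame with columns ``timestamp`` (datetime64[ns],
    UTC), ``lon``, ``lat`` plus any number of numeric weather columns.
    Fixes are strictly increasing in timestamp.
    """

    individual_id: str
    population: str
    fixes: pd.DataFrame

    def __post_init__(self) -> None:
        ts = self.fixes["timestamp"]
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            raise ValueError("fixes must be sorted by timestamp")
        lat = self.fixes["lat"].to_numpy(float)
        lon = self.fixes["lon"].to_numpy(float)
        if len(lat) and (np.nanmin(lat) < -90 or np.nanmax(lat) > 90):
            raise ValueError("latitude out of [-90, 90]")
        if len(lon) and (np.nanmin(lon) <= -180 or np.nanmax(lon) > 180):
            raise ValueError("longitude out of (-180, 180]")

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    @property
    def weather_columns(self) -> list[str]:
        return [c for c in self.fixes.columns
                if c not in ("timestamp", "lon", "lat")]

    @property
    def start(self) -> pd.Timestamp:
        return self.fixes["timestamp"].iloc[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.fixes["timestamp"].iloc[-1]

    def slice_time(self, start: pd.Timestamp, end: pd.Timestamp) -> "Track":
        """Sub-track with start <= timestamp <= end."""
        m = (self.fixes["timestamp"] >= start) & (self.fixes["timestamp"] <= end)
        return Track(self.individual_id, self.population,
                     self.fixes.loc[m].reset_index(drop=True))


@dataclass
class Migration:
    """One delimited migration of one individual."""

    individual_id: str
    population: str
    season: str  # "spring" | "fall"
    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        if self.season not in ("spring", "fall"):
            raise ValueError(f"season must be 'spring' or 'fall', got {self.season!r}")
        if not self.start < self.end:
            raise ValueError("migration start must precede end")


@dataclass
class ReadReport:
    """Bookkeeping from CSV ingestion."""

    n_rows: int = 0
    n_dropped_missing_coords: int = 0
    n_dropped_duplicate_ts: int = 0
    bad_rows: list = field(default_factory=list)


def read_movebank_csv(path, column_map: dict[str, str] | None = None,
                      report: ReadReport | None = None) -> list[Track]:
    """Read a Movebank-dialect CSV into one :class:`Track` per individual.

    Parameters
    ----------
    path : str or file-like
        CSV with at least timestamp, location-long, location-lat and
        individual-local-identifier columns.
    column_map : dict, optional
        Mapping of nonstandard header -> Movebank header, applied before
        validation (e.g. ``{"long": "location-long"}``).
    report : ReadReport, optional
        If given, filled with drop counts.

    Rows with missing coordinates are dropped (counted in the report and a
    log record); duplicate timestamps within an individual keep the first
    fix.  Extra numeric columns are preserved as weather covariates.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)

    for col in MOVEBANK_COLUMNS:
        if col not in df.columns:
            raise TrackFormatError(f"missing mandatory column: {col!r}")
    df = df.rename(columns=MOVEBANK_COLUMNS)

    rep = report if report is not None else ReadReport()
    rep.n_rows = len(df)

    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="mixed")
    except (ValueError, TypeError):
        # find the offending row for a useful error message
        parsed = pd.to_datetime(df["timestamp"], format="mixed", errors="coerce")
        bad = np.flatnonzero(parsed.isna() & df["timestamp"].notna())
        line = int(bad[0]) + 2 if len(bad) else -1  # +2: header + 1-based
        raise TrackFormatError(f"unparseable timestamp at line {line}")

    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    ok = df["lon"].notna() & df["lat"].notna() & df["timestamp"].notna()
    rep.n_dropped_missing_coords = int((~ok).sum())
    if rep.n_dropped_missing_coords:
        logger.warning("dropped %d rows with missing coordinates/timestamps",
                       rep.n_dropped_missing_coords)
    df = df.loc[ok]

    has_population = "population" in df.columns
    weather_cols = [c for c in df.columns
                    if c not in set(MOVEBANK_COLUMNS.values())
                    and c not in ("lon", "lat", "individual_id", "timestamp")
                    and c not in META_COLUMNS
                    and pd.api.types.is_numeric_dtype(df[c])]

    tracks = []
    for ind, g in df.groupby("individual_id", sort=True):
        g = g.sort_values("timestamp", kind="mergesort")
        dup = g["timestamp"].duplicated(keep="first")
        if dup.any():
            rep.n_dropped_duplicate_ts += int(dup.sum())
            warnings.warn(f"individual {ind}: dropped {int(dup.sum())} "
                          "duplicate-timestamp fixes (kept first)")
            g = g.loc[~dup]
        population = str(g["population"].iloc[0]) if has_population else ""
        fixes = g[["timestamp", "lon", "lat"] + weather_cols].reset_index(drop=True)
        tracks.append(Track(str(ind), population, fixes))
    return tracks


def read_migrations_csv(path) -> list[Migration]:
    """Read a migration table (individual_id, population, season, start, end)."""
    df = pd.read_csv(path)
    needed = {"individual_id", "season", "start", "end"}
    missing = needed - set(df.columns)
    if missing:
        raise TrackFormatError(f"migration table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(Migration(
            individual_id=str(row["individual_id"]),
            population=str(row.get("population", "")),
            season=str(row["season"]),
            start=pd.Timestamp(row["start"]),
            end=pd.Timestamp(row["end"]),
        ))
    return out


def mean_fix_interval_h(track: Track) -> float:
    """Arithmetic mean of inter-fix gaps, in hours."""
    ts = track.fixes["timestamp"].to_numpy()
    if len(ts) < 2:
        return np.inf
    gaps = np.diff(ts).astype("timedelta64[s]").astype(float) / 3600.0
    return float(gaps.mean())


def filter_regular_migrations(tracks: list[Track], migrations: list[Migration],
                              max_mean_interval_h: float = 3.0,
                              ) -> list[tuple[Track, Migration]]:
    """Keep only migration slices sampled regularly enough.

    A slice is retained iff its mean inter-fix interval is strictly below
    ``max_mean_interval_h`` (default 3 h).  Migrations with fewer than two
    fixes are excluded with a warning.
    """
    if max_mean_interval_h <= 0:
        raise ValueError("max_mean_interval_h must be positive")
    by_id = {t.individual_id: t for t in tracks}
    out = []
    for mig in migrations:
        track = by_id.get(mig.individual_id)
        if track is None:
            warnings.warn(f"no track for individual {mig.individual_id}; skipped")
            continue
        sl = track.slice_time(mig.start, mig.end)
        if sl.n_fixes < 2:
            warnings.warn(f"migration {mig.individual_id}/{mig.season} "
                          f"{mig.start:%Y-%m-%d} has < 2 fixes; excluded")
            continue
        if mean_fix_interval_h(sl) < max_mean_interval_h:
            out.append((sl, mig))
    return out


STOPOVER_CSV_COLUMNS = ["individual_id", "population", "season", "start", "end",
                        "duration_h", "provenance", "prop_activity",
                        "total_distance_km"]


def write_stopovers_csv(stopovers, path) -> None:
    """Write stopover intervals to CSV (one row each; ISO 8601 UTC times).

    Accepts StopoverInterval-like objects; activity fields may be absent
    (written empty).  Writing is idempotent.
    """
    rows = []
    for s in stopovers:
        rows.append({
            "individual_id": s.individual_id,
            "population": s.population,
            "season": s.season,
            "start": pd.Timestamp(s.start).strftime("%Y-%m-%d %H:%M:%S"),
            "end": pd.Timestamp(s.end).strftime("%Y-%m-%d %H:%M:%S"),
            "duration_h": round(float(s.duration_h), 6),
            "provenance": s.provenance,
            "prop_activity": getattr(s, "prop_activity", None),
            "total_distance_km": getattr(s, "total_distance_km", None),
        })
    pd.DataFrame(rows, columns=STOPOVER_CSV_COLUMNS).to_csv(path, index=False)


def read_stopovers_csv(path) -> pd.DataFrame:
    """Read back a stopover CSV with parsed timestamps."""
    df = pd.read_csv(path)
    for col in ("start", "end"):
        df[col] = pd.to_datetime(df[col])
    return df


def split_migrations_by_displacement(track: Track, population: str = "",
                                     min_days: int = 3,
                                     min_daily_advance_km: float = 50.0,
                                     ) -> list[Migration]:
    """Convenience net-displacement splitter (NOT part of the validated pipeline).

    A migration is a maximal run of days each advancing the great-circle
    distance from the track origin by at least ``min_daily_advance_km``.
    Season is assigned by hemisphere-agnostic direction of travel: poleward
    = spring, equatorward = fall.
    """
    from .regularize import haversine_km

    f = track.fixes
    if len(f) < 2:
        return []
    days = f["timestamp"].dt.floor("D")
    daily = f.groupby(days).agg(lon=("lon", "last"), lat=("lat", "last"))
    origin = (f["lon"].iloc[0], f["lat"].iloc[0])
    disp = haversine_km(origin[0], origin[1],
                        daily["lon"].to_numpy(), daily["lat"].to_numpy())
    advance = np.diff(disp, prepend=0.0)
    moving = advance >= min_daily_advance_km

    out: list[Migration] = []
    i = 0
    idx = daily.index
    while i < len(moving):
        if not moving[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(moving) and moving[j + 1]:
            j += 1
        if j - i + 1 >= min_days:
            start, end = idx[i], idx[j] + pd.Timedelta(days=1)
            dlat = daily["lat"].iloc[j] - daily["lat"].iloc[i]
            hemi = np.sign(daily["lat"].iloc[i]) or 1.0
            season = "spring" if dlat * hemi > 0 else "fall"
            out.append(Migration(track.individual_id, population or track.population,
                                 season, start, end))
        i = j + 1
    return out
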