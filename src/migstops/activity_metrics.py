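"""Per-stopover movement-activity summaries and the most-active-third cut.

"Daytime" here means the non-roosting window (default 08:00-17:00 local
solar); activity is strictly more than 1 km/h between consecutive hourly
fixes.  This window is deliberately distinct from the sun-up daylight flag
used by the rejection filter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .regularize import RegularTrack, haversine_km
from .solar_clock import SolarContext, roost_flags
from .stopover_segmentation import StopoverInterval


@dataclass
class ActivitySummary:
    stopover: StopoverInterval
    n_daytime_h: int
    n_active_h: int
    prop_activity: float  # NaN when no daytime hours
    total_distance_km: float


def proportion_activity(interval: StopoverInterval, rt: RegularTrack,
                        ctx: SolarContext = SolarContext(),
                        activity_speed_kmh: float = 1.0) -> ActivitySummary:
    """Activity summary for one stopover.

    Daytime hours are the interval's fixes outside roosting hours; active
    hours are daytime fixes with speed strictly above
    ``activity_speed_kmh``.  ``total_distance_km`` sums consecutive
    haversine steps inside the interval.  The summary is also written onto
    the interval object (``prop_activity`` etc.) for CSV export.
    """
    ts = rt.times
    m = (ts >= np.datetime64(interval.start)) & (ts <= np.datetime64(interval.end))
    idx = np.flatnonzero(m)
    if len(idx) == 0:
        raise ValueError("interval contains no fixes of this track")

    roost = roost_flags(ts[idx], rt.lon[idx], ctx)
    daytime = ~roost
    speeds = rt.speed_kmh[idx]
    active = daytime & np.isfinite(speeds) & (speeds > activity_speed_kmh)

    n_day = int(daytime.sum())
    n_act = int(active.sum())
    if n_day == 0:
        warnings.warn("stopover has zero daytime hours; prop_activity undefined")
        prop = float("nan")
    else:
        prop = n_act / n_day

    if len(idx) >= 2:
        lon, lat = rt.lon[idx], rt.lat[idx]
        dist = float(np.sum(haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])))
    else:
        dist = 0.0

    interval.n_daytime_h = n_day
    interval.n_active_h = n_act
    interval.prop_activity = prop
    interval.total_distance_km = dist
    return ActivitySummary(interval, n_day, n_act, prop, dist)


def exclude_most_active_third(summaries: list[ActivitySummary],
                              rounding: str = "ceil",
                              ) -> tuple[list[ActivitySummary], list[ActivitySummary]]:
    """Split stopovers into (retained, excluded) by proportion of activity.

    Excludes the most active third (ceil(n/3) by default; ``rounding`` may
    be "floor" or "round").  Ties at the cut are broken by excluding higher
    total distance first, then earlier start time first.  Stopovers with
    undefined prop_activity are never excluded and sort to the bottom.
    """
    defined = [s for s in summaries if not math.isnan(s.prop_activity)]
    if len(defined) < 3:
        raise ValueError("need at least 3 stopovers with defined activity")
    n = len(defined)
    if rounding == "ceil":
        k = math.ceil(n / 3)
    elif rounding == "floor":
        k = math.floor(n / 3)
    elif rounding == "round":
        k = round(n / 3)
    else:
        raise ValueError(f"unknown rounding: {rounding!r}")

    order = sorted(defined, key=lambda s: (-s.prop_activity,
                                           -s.total_distance_km,
                                           s.stopover.start))
    excluded = order[:k]
    retained = order[k:] + [s for s in summaries if math.isnan(s.prop_activity)]
    return retained, excluded
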