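"""End-to-end orchestration: detection, activity, alignment, models, report."""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import event_aligned_weather as eaw
from .activity_metrics import (ActivitySummary, exclude_most_active_third,
                               proportion_activity)
from .inferential_models import (DEFAULT_PREDICTOR_PRIORITY,
                                 fit_activity_glmm, fit_stopover_count_model,
                                 prune_correlated_predictors)
from .regularize import RegularTrack, regularize_track
from .solar_clock import SolarContext
from .stopover_segmentation import (SegmentationConfig, StageCounts,
                                    StopoverInterval, segment_stopovers)
from .track_model import Migration, Track, filter_regular_migrations


@dataclass
class AnalysisConfig:
    window_before_h: int = 7
    window_after_h: int = 7
    loess_span: float = 0.5
    correlation_threshold: float = 0.6
    predictor_priority: tuple[str, ...] = DEFAULT_PREDICTOR_PRIORITY
    exclusion_rounding: str = "ceil"
    max_mean_interval_h: float = 3.0
    max_gap_h: float = 24.0


@dataclass
class RunReport:
    """Machine-readable bookkeeping across all filtering stages."""

    n_migrations_in: int = 0
    n_migrations_regular: int = 0
    stage_counts: dict = field(default_factory=dict)
    n_stopovers: int = 0
    n_excluded_most_active: int = 0
    n_retained_for_alignment: int = 0
    n_incomplete_weather: int = 0
    n_glmm_rows: int = 0
    per_migration: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def regular_migration_tracks(tracks: list[Track], migrations: list[Migration],
                             analysis: AnalysisConfig | None = None,
                             ) -> list[tuple[RegularTrack, Migration]]:
    """Slice, sampling-filter and hourly-regularize every migration."""
    a = analysis or AnalysisConfig()
    out = []
    for sl, mig in filter_regular_migrations(tracks, migrations,
                                             a.max_mean_interval_h):
        for rt in regularize_track(sl, season=mig.season, max_gap_h=a.max_gap_h):
            rt.population = mig.population or rt.population
            out.append((rt, mig))
    return out


def detect_stopovers(tracks: list[Track], migrations: list[Migration],
                     seg: SegmentationConfig | None = None,
                     analysis: AnalysisConfig | None = None,
                     report: RunReport | None = None,
                     ) -> tuple[list[StopoverInterval], list[tuple[RegularTrack, Migration]]]:
    """Detection across all migrations, with stage-count bookkeeping."""
    seg = seg or SegmentationConfig()
    rep = report if report is not None else RunReport()
    rep.n_migrations_in = len(migrations)
    pairs = regular_migration_tracks(tracks, migrations, analysis)
    rep.n_migrations_regular = len({(m.individual_id, m.season, str(m.start))
                                    for _, m in pairs})
    stopovers: list[StopoverInterval] = []
    total = StageCounts()
    for rt, mig in pairs:
        found, counts = segment_stopovers(rt, seg)
        stopovers.extend(found)
        total = total + counts
        rec = counts.as_dict()
        rec.update(individual_id=mig.individual_id, season=mig.season,
                   migration_start=str(mig.start))
        rep.per_migration.append(rec)
    rep.stage_counts = total.as_dict()
    rep.stage_counts.pop("chosen_radius_m", None)
    rep.n_stopovers = len(stopovers)
    stopovers.sort(key=lambda s: (s.individual_id, s.start))
    return stopovers, pairs


def _rt_for(stopover: StopoverInterval,
            pairs: list[tuple[RegularTrack, Migration]]) -> RegularTrack | None:
    for rt, mig in pairs:
        if (mig.individual_id == stopover.individual_id
                and mig.season == stopover.season and len(rt)):
            t0, t1 = rt.times[0], rt.times[-1]
            if (np.datetime64(stopover.start) >= t0
                    and np.datetime64(stopover.start) <= t1):
                return rt
    return None


def activity_stage(stopovers: list[StopoverInterval],
                   pairs: list[tuple[RegularTrack, Migration]],
                   ctx: SolarContext | None = None,
                   activity_speed_kmh: float = 1.0,
                   rounding: str = "ceil",
                   report: RunReport | None = None,
                   ) -> tuple[list[ActivitySummary], list[ActivitySummary]]:
    """Per-stopover activity plus the most-active-third exclusion."""
    ctx = ctx or SolarContext()
    summaries = []
    for s in stopovers:
        rt = _rt_for(s, pairs)
        if rt is None:
            continue
        summaries.append(proportion_activity(s, rt, ctx, activity_speed_kmh))
    retained, excluded = exclude_most_active_third(summaries, rounding)
    if report is not None:
        report.n_excluded_most_active = len(excluded)
        report.n_retained_for_alignment = len(retained)
    return retained, excluded


def aligned_weather_stage(retained: list[ActivitySummary],
                          pairs: list[tuple[RegularTrack, Migration]],
                          analysis: AnalysisConfig | None = None,
                          report: RunReport | None = None,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Start- and end-aligned change curves and peak lags per variable."""
    a = analysis or AnalysisConfig()
    curves_out, lags_out = [], []
    variables = set()
    for s in retained:
        rt = _rt_for(s.stopover, pairs)
        if rt is not None:
            variables.update(rt.weather_columns)
    incomplete = 0
    for event_kind in ("start", "end"):
        for var in sorted(variables):
            windows, ids = [], []
            for s in retained:
                rt = _rt_for(s.stopover, pairs)
                if rt is None or var not in rt.fixes.columns:
                    continue
                series = eaw.hourly_change(rt.fixes[var].to_numpy(float))
                event_time = getattr(s.stopover, event_kind)
                w = eaw.extract_event_window(series, rt.times, event_time,
                                             a.window_before_h, a.window_after_h)
                if np.isfinite(w).any():
                    windows.append(w)
                    ids.append(s.stopover.individual_id)
                else:
                    incomplete += 1
            if not windows:
                continue
            curve = eaw.average_curves(windows, ids, variable=var,
                                       before_h=a.window_before_h,
                                       after_h=a.window_after_h)
            curve = eaw.loess_smooth(curve, span=a.loess_span)
            lag = eaw.peak_lag(curve, event_kind)
            cf = eaw.curves_to_frame([curve])
            cf["event_kind"] = event_kind
            curves_out.append(cf)
            lags_out.append(lag)
    if report is not None:
        report.n_incomplete_weather = incomplete
    curves = (pd.concat(curves_out, ignore_index=True)
              if curves_out else pd.DataFrame())
    return curves, eaw.lags_to_frame(lags_out)


def models_stage(stopovers: list[StopoverInterval], migrations: list[Migration],
                 retained: list[ActivitySummary],
                 pairs: list[tuple[RegularTrack, Migration]],
                 analysis: AnalysisConfig | None = None,
                 report: RunReport | None = None,
                 ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Fit the count LMM and the activity GLMM; return coefficient tables."""
    a = analysis or AnalysisConfig()

    rows = []
    for mig in migrations:
        n = sum(1 for s in stopovers
                if s.individual_id == mig.individual_id
                and s.season == mig.season
                and mig.start <= s.start <= mig.end + pd.Timedelta(days=2))
        rows.append({"individual_id": mig.individual_id,
                     "population": mig.population, "season": mig.season,
                     "count": n})
    count_df = pd.DataFrame(rows)
    count_res = fit_stopover_count_model(count_df)

    glmm_rows = []
    for s in retained:
        rt = _rt_for(s.stopover, pairs)
        if rt is None or s.n_daytime_h == 0 or math.isnan(s.prop_activity):
            continue
        ts = rt.times
        m = ((ts >= np.datetime64(s.stopover.start))
             & (ts <= np.datetime64(s.stopover.end)))
        row = {"individual_id": s.stopover.individual_id,
               "population": s.stopover.population,
               "n_active_h": s.n_active_h, "n_daytime_h": s.n_daytime_h}
        complete = True
        for var in rt.weather_columns:
            v = rt.fixes[var].to_numpy(float)[m]
            if not np.isfinite(v).any():
                complete = False
                break
            row[var] = float(np.nanmean(v))
        if complete:
            glmm_rows.append(row)
    glmm_df = pd.DataFrame(glmm_rows)
    if report is not None:
        report.n_glmm_rows = len(glmm_df)

    predictor_cols = [c for c in glmm_df.columns
                      if c not in ("individual_id", "population",
                                   "n_active_h", "n_daytime_h")]
    retained_preds = prune_correlated_predictors(
        glmm_df[predictor_cols], list(a.predictor_priority),
        a.correlation_threshold)
    glmm_res = fit_activity_glmm(glmm_df, retained_preds)
    return count_res.summary_frame(), glmm_res.summary_frame(), retained_preds
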