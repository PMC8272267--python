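import numpy as np
import pandas as pd
import pytest

from migstops.fpt_core import FPTProfile
from migstops.stopover_segmentation import (SegmentationConfig, StageCounts,
                                            StopoverInterval, buffer_rescue,
                                            detect_candidates, fpt_threshold,
                                            merge_intervals, reject_filters,
                                            roost_start_adjust,
                                            segment_stopovers, trim_endpoints)

from conftest import make_regular_track, track_from_steps


def _profile(log_fpts):
    fpt = np.exp(np.asarray(log_fpts, dtype=float))
    logs = np.log(fpt[np.isfinite(fpt)])
    lv = float(np.var(logs, ddof=1)) if len(logs) > 1 else np.nan
    return FPTProfile(radius_m=3000.0, fpt_h=fpt, log_var=lv)


class TestThreshold:
    def test_hand_arithmetic(self):
        # logs {0,0,0,4,4}: mean 1.6, sample sd 2.19089
        thr = fpt_threshold(_profile([0, 0, 0, 4, 4]), c=1.0)
        assert thr == pytest.approx(1.6 + 2.1908902300206643, rel=1e-12)

    def test_c_zero_is_mean(self):
        assert fpt_threshold(_profile([0, 0, 0, 4, 4]), c=0.0) == \
            pytest.approx(1.6)

    def test_constant_fpt(self):
        assert fpt_threshold(_profile([2.5, 2.5, 2.5]), c=1.0) == \
            pytest.approx(2.5)

    def test_degenerate_raises(self):
        prof = FPTProfile(3000.0, np.array([np.nan, 1.0, np.nan]), np.nan)
        with pytest.raises(ValueError, match="degenerate"):
            fpt_threshold(prof)


class TestDetectCandidates:
    def test_nothing_above(self):
        assert detect_candidates(_profile([0, 0, 0]), 1.0) == []

    def test_single_run_fencepost(self):
        runs = detect_candidates(_profile([0, 3, 3, 3, 3, 3, 0]), 1.0)
        assert runs == [(1, 5)]  # 5 fixes -> spans 4 h

    def test_two_runs_split_by_dip(self):
        runs = detect_candidates(_profile([3, 3, 0, 3, 3]), 1.0)
        assert runs == [(0, 1), (3, 4)]

    def test_missing_breaks_runs(self):
        prof = FPTProfile(3000.0,
                          np.array([20.0, 20.0, np.nan, 20.0]), 0.1)
        assert detect_candidates(prof, 1.0) == [(0, 1), (3, 3)]

    def test_strictly_above(self):
        assert detect_candidates(_profile([1.0, 1.0]), 1.0) == []


class TestTrimEndpoints:
    def test_fast_first_fix_trimmed(self):
        rt = track_from_steps([40, 1, 1, 1, 1, 1], [180] * 6, lat0=0.0)
        assert trim_endpoints((0, 4), rt) == (1, 4)

    def test_fast_last_fix_trimmed(self):
        rt = track_from_steps([1, 1, 1, 1, 50, 1], [180] * 6, lat0=0.0)
        assert trim_endpoints((0, 4), rt) == (0, 3)

    def test_equal_speeds_untouched(self):
        rt = track_from_steps([5] * 6, [180] * 6, lat0=0.0)
        assert trim_endpoints((0, 4), rt) == (0, 4)

    def test_short_run_untouched(self):
        rt = track_from_steps([40, 1, 1], [180] * 3, lat0=0.0)
        assert trim_endpoints((0, 1), rt) == (0, 1)


def _iv(start, end, **kw):
    defaults = dict(individual_id="b0", population="pop", season="fall",
                    provenance="fpt")
    defaults.update(kw)
    return StopoverInterval(start=pd.Timestamp(start), end=pd.Timestamp(end),
                            **defaults)


class TestRejectFilters:
    def _equator_track(self, t0, n):
        # equator, lon 0: local solar ~ UTC; daylight ~ 05:56-18:04 on equinox
        return make_regular_track(np.zeros(n), np.zeros(n), t0=t0)

    def test_too_short_rejected(self):
        rt = self._equator_track("2015-03-20 10:00:00", 6)
        kept, rej = reject_filters(
            [_iv("2015-03-20 10:00:00", "2015-03-20 11:30:00")], rt)
        assert kept == [] and rej[0][1] == "duration"

    def test_low_daylight_rejected(self):
        # fixes 17:00..02:00: only 17:00 and 18:00 are in daylight (2/10)
        rt = self._equator_track("2015-03-20 15:00:00", 14)
        kept, rej = reject_filters(
            [_iv("2015-03-20 17:00:00", "2015-03-21 02:00:00")], rt)
        assert kept == [] and rej[0][1] == "daylight"

    def test_passing_candidate_kept(self):
        # fixes 14:00..23:00: daylight 14..18 -> 5/10, duration 9 h
        rt = self._equator_track("2015-03-20 12:00:00", 14)
        kept, rej = reject_filters(
            [_iv("2015-03-20 14:00:00", "2015-03-20 23:00:00")], rt)
        assert len(kept) == 1 and rej == []


class TestBufferRescue:
    def _cluster_track(self, n, spread_deg=0.01):
        rng = np.random.default_rng(4)
        lon = -100 + rng.uniform(-spread_deg, spread_deg, n)
        lat = 40 + rng.uniform(-spread_deg, spread_deg, n)
        return make_regular_track(lon, lat)

    def test_31_points_within_2km_is_stopover(self):
        out = buffer_rescue(self._cluster_track(31), [])
        assert len(out) == 1
        assert out[0].provenance == "buffer"
        assert out[0].duration_h == pytest.approx(30.0)

    def test_exactly_30_points_is_not(self):
        assert buffer_rescue(self._cluster_track(30), []) == []

    def test_directed_track_has_none(self):
        rt = track_from_steps([20] * 40, [180] * 40)
        assert buffer_rescue(rt, []) == []

    def test_kept_intervals_are_skipped(self):
        rt = self._cluster_track(40)
        ts = rt.times
        kept = [_iv(pd.Timestamp(ts[0]), pd.Timestamp(ts[20]))]
        out = buffer_rescue(rt, kept)
        assert out == []  # remaining 19 uncovered fixes are not > 30


class TestRoostStartAdjust:
    def _track_stop_at(self, stop_hour: int, t0="2015-03-20 00:00:00", n=40):
        # lon 0 so local solar == UTC; bird moves 30 km/h until stop_hour
        steps = [30.0 if h < stop_hour else 0.0 for h in range(n - 1)]
        return track_from_steps(steps, [180] * (n - 1), lat0=0.0, lon0=0.0,
                                t0=t0)

    def test_evening_cessation_moves_to_next_morning(self):
        # moving through 18:00->19:00, stationary after: cessation fix 18:00
        rt = self._track_stop_at(19)
        out = roost_start_adjust(pd.Timestamp("2015-03-20 21:00:00"),
                                 pd.Timestamp("2015-03-21 12:00:00"), rt)
        assert out[0] == pd.Timestamp("2015-03-21 08:00:00")

    def test_afternoon_cessation_unchanged(self):
        rt = self._track_stop_at(14)
        start = pd.Timestamp("2015-03-20 15:00:00")
        out = roost_start_adjust(start, pd.Timestamp("2015-03-21 12:00:00"), rt)
        assert out[0] == start

    def test_predawn_cessation_same_morning(self):
        rt = self._track_stop_at(7)
        out = roost_start_adjust(pd.Timestamp("2015-03-20 07:00:00"),
                                 pd.Timestamp("2015-03-20 15:00:00"), rt)
        assert out[0] == pd.Timestamp("2015-03-20 08:00:00")

    def test_adjusted_past_end_discards(self):
        rt = self._track_stop_at(19)
        out = roost_start_adjust(pd.Timestamp("2015-03-20 21:00:00"),
                                 pd.Timestamp("2015-03-21 03:00:00"), rt)
        assert out is None


class TestMerge:
    def test_adjacent_within_one_hour_merged(self):
        rt = make_regular_track(np.zeros(30), np.zeros(30),
                                t0="2015-03-20 00:00:00")
        a = _iv("2015-03-20 02:00:00", "2015-03-20 06:00:00")
        b = _iv("2015-03-20 07:00:00", "2015-03-20 10:00:00",
                provenance="buffer")
        merged, n = merge_intervals([a, b], rt)
        assert n == 1 and len(merged) == 1
        assert merged[0].provenance == "fpt"
        assert merged[0].end == pd.Timestamp("2015-03-20 10:00:00")

    def test_distant_intervals_untouched(self):
        rt = make_regular_track(np.zeros(40), np.zeros(40),
                                t0="2015-03-20 00:00:00")
        a = _iv("2015-03-20 02:00:00", "2015-03-20 06:00:00")
        b = _iv("2015-03-20 12:00:00", "2015-03-20 15:00:00")
        merged, n = merge_intervals([a, b], rt)
        assert n == 0 and len(merged) == 2


def _migration_track(front=None, n_days=6, lon0=0.0, t0="2015-10-20 00:00:00"):
    """Hand-built migration at lon ~0: roost 17-08, flight 08-17 at 35 km/h.

    ``front`` is an (start_hour_index, duration_h) forced-immobility bout.
    """
    n = n_days * 24
    t0 = pd.Timestamp(t0)
    rng = np.random.default_rng(99)
    steps, bearings = [], []
    for h in range(n - 1):
        hour = (t0 + pd.Timedelta(hours=h)).hour
        grounded = front is not None and front[0] <= h < front[0] + front[1]
        if grounded or hour >= 17 or hour < 8:
            steps.append(abs(rng.normal(0, 0.02)))
        else:
            steps.append(abs(rng.normal(35, 3)))
        bearings.append(rng.normal(180, 4))
    return track_from_steps(steps, bearings, lat0=42.0, lon0=lon0, t0=t0)


class TestSegmentStopovers:
    def test_purely_directed_migration_has_no_stopovers(self):
        rt = _migration_track()
        stops, counts = segment_stopovers(rt)
        assert stops == []
        assert counts.conserved()

    def test_48h_bout_recovered_within_one_hour(self):
        # front begins day 3 at 10:00 local and lasts 48 h
        start_h = 2 * 24 + 10
        rt = _migration_track(front=(start_h, 48), n_days=8)
        stops, counts = segment_stopovers(rt)
        assert len(stops) == 1
        true_start = pd.Timestamp("2015-10-22 10:00:00")
        true_end = true_start + pd.Timedelta(hours=48)
        assert abs((stops[0].start - true_start).total_seconds()) <= 3600
        assert abs((stops[0].end - true_end).total_seconds()) <= 3600
        assert stops[0].provenance == "fpt"

    def test_forage_bout_recovered_via_buffer(self):
        # slow tortuous bout, < 15 km extent, 41 fixes; FPT route disabled
        # by an absurdly high threshold so only buffer rescue can find it
        t0 = pd.Timestamp("2015-10-20 00:00:00")
        rng = np.random.default_rng(12)
        steps, bearings = [], []
        start_h, dur = 2 * 24 + 9, 41
        for h in range(8 * 24 - 1):
            hour = (t0 + pd.Timedelta(hours=h)).hour
            if start_h <= h < start_h + dur:
                steps.append(rng.uniform(2, 4))
                bearings.append(rng.uniform(0, 360))
            elif hour >= 17 or hour < 8:
                steps.append(abs(rng.normal(0, 0.02)))
                bearings.append(rng.uniform(0, 360))
            else:
                steps.append(abs(rng.normal(35, 3)))
                bearings.append(rng.normal(180, 4))
        rt = track_from_steps(steps, bearings, lat0=42.0, lon0=0.0, t0=t0)
        cfg = SegmentationConfig(threshold_c=50.0)
        stops, counts = segment_stopovers(rt, cfg)
        assert counts.n_kept_fpt == 0
        assert any(s.provenance == "buffer" for s in stops)
        buf = next(s for s in stops if s.provenance == "buffer")
        assert abs((buf.start - (t0 + pd.Timedelta(hours=start_h)))
                   .total_seconds()) <= 2 * 3600

    def test_outputs_disjoint_and_long_enough(self, small_dataset):
        from migstops.pipeline import detect_stopovers
        _, tracks, migrations, _, _ = small_dataset
        stops, _ = detect_stopovers(tracks, migrations)
        by_ind: dict = {}
        for s in stops:
            assert s.duration_h >= 2.0
            by_ind.setdefault((s.individual_id, s.season), []).append(s)
        for ivs in by_ind.values():
            ivs.sort(key=lambda s: s.start)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end < b.start

    def test_determinism(self):
        rt = _migration_track(front=(2 * 24 + 10, 30), n_days=7)
        s1, c1 = segment_stopovers(rt)
        s2, c2 = segment_stopovers(rt)
        assert [(s.start, s.end, s.provenance) for s in s1] == \
            [(s.start, s.end, s.provenance) for s in s2]
        assert c1.as_dict() == c2.as_dict()

    def test_degenerate_track_warns_empty(self):
        rt = make_regular_track(np.zeros(8), np.full(8, 40.0))
        with pytest.warns(UserWarning):
            stops, counts = segment_stopovers(rt)
        assert stops == [] and counts.n_final == 0


class TestStageCounts:
    def test_addition(self):
        a = StageCounts(n_candidates=3, n_kept_fpt=2, n_rejected_duration=1)
        b = StageCounts(n_candidates=2, n_kept_fpt=1, n_rejected_daylight=1)
        c = a + b
        assert c.n_candidates == 5 and c.n_kept_fpt == 3
        assert c.conserved()
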