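"""GPS clustering, speed matching, diel composition, actograms, sun times."""
from datetime import date, datetime, timezone

import numpy as np
import pandas as pd
import pytest

import burstclass as bc
from burstclass._solar import sunrise_sunset
from burstclass.errors import DegenerateIntervalError
from burstclass.field_validation import EARTH_RADIUS_M

T0 = pd.Timestamp("2023-03-20T00:00:00Z")


def _fix(minutes, lat, lon):
    return bc.GpsFix("a", T0 + pd.Timedelta(minutes=minutes), lat, lon)


def _fixes_at_meters(offsets_m, step_min=4.0, lat0=52.0, lon0=13.0):
    """Fixes displaced east by the given metre offsets."""
    m_per_deg = np.radians(1) * EARTH_RADIUS_M * np.cos(np.radians(lat0))
    return [_fix(i * step_min, lat0, lon0 + d / m_per_deg)
            for i, d in enumerate(offsets_m)]


def _record(minutes, behaviour, bid=None):
    return bc.PredictionRecord(
        burst_id=bid or f"p{minutes}", burst_start=T0 + pd.Timedelta(minutes=minutes),
        window_probs=np.empty((0, 0)), window_classes=[],
        burst_class=behaviour, vote_fraction=1.0)


class TestHaversine:
    def test_matches_spherical_law_of_cosines_oracle(self, rng):
        for _ in range(50):
            lat1, lat2 = rng.uniform(-80, 80, 2)
            lon1, lon2 = rng.uniform(-179, 179, 2)
            p1, p2 = np.radians([lat1, lat2])
            dl = np.radians(lon2 - lon1)
            cosc = np.clip(np.sin(p1) * np.sin(p2)
                           + np.cos(p1) * np.cos(p2) * np.cos(dl), -1, 1)
            oracle = EARTH_RADIUS_M * np.arccos(cosc)
            got = bc.haversine_m(lat1, lon1, lat2, lon2)
            assert got == pytest.approx(oracle, rel=1e-3, abs=1e-3)

    def test_zero_distance(self):
        assert bc.haversine_m(52.5, 13.4, 52.5, 13.4) == 0.0


class TestSegmentClusters:
    def test_all_within_radius_single_cluster(self):
        fixes = _fixes_at_meters([0, 10, 20, 30, 45])
        clusters = bc.segment_clusters(fixes, 50)
        assert len(clusters) == 1 and len(clusters[0]) == 5

    def test_spread_line_gives_singletons(self):
        fixes = _fixes_at_meters([0, 60, 120])
        clusters = bc.segment_clusters(fixes, 50)
        assert [len(c) for c in clusters] == [1, 1, 1]

    def test_distance_measured_to_anchor_not_previous(self):
        # 0, 40, 80: third is 40 m from second but 80 m from the anchor
        fixes = _fixes_at_meters([0, 40, 80])
        clusters = bc.segment_clusters(fixes, 50)
        assert [len(c) for c in clusters] == [2, 1]

    def test_partition_and_oracle_equivalence_on_random_walk(self, rng):
        steps = rng.normal(0, 30, size=100).cumsum()
        fixes = _fixes_at_meters(steps)
        clusters = bc.segment_clusters(fixes, 50)
        assert sum(len(c) for c in clusters) == len(fixes)
        # independent re-implementation of the rule
        expected = []
        for f in fixes:
            if expected and bc.haversine_m(expected[-1][0].lat, expected[-1][0].lon,
                                           f.lat, f.lon) <= 50:
                expected[-1].append(f)
            else:
                expected.append([f])
        assert [len(c) for c in clusters] == [len(g) for g in expected]

    def test_empty_input(self):
        assert bc.segment_clusters([]) == []


class TestClusterCoherence:
    def test_resting_inside_stationary_bout_is_fully_clustered(self):
        fixes = _fixes_at_meters([0] * 8 + [200, 400, 600])
        records = [_record(2 * i, "resting") for i in range(14)]  # inside bout
        clusters = bc.segment_clusters(fixes, 50)
        coherence = bc.cluster_behaviour_coherence(records, clusters, min_items=10)
        assert coherence["resting"] == 1.0

    def test_cluster_below_min_items_contributes_nothing(self):
        fixes = _fixes_at_meters([0] * 8 + [500])
        records = [_record(2 * i, "resting") for i in range(9)]
        clusters = bc.segment_clusters(fixes, 50)
        coherence = bc.cluster_behaviour_coherence(records, clusters, min_items=10)
        assert coherence["resting"] == 0.0

    def test_fast_track_all_singletons_gives_zero(self):
        fixes = _fixes_at_meters(np.arange(10) * 120.0)
        records = [_record(4 * i + 1, "trotting") for i in range(9)]
        clusters = bc.segment_clusters(fixes, 50)
        coherence = bc.cluster_behaviour_coherence(records, clusters, min_items=10)
        assert coherence["trotting"] == 0.0

    def test_lowering_min_items_never_decreases_proportion(self):
        fixes = _fixes_at_meters([0] * 6 + [300] * 5 + [900])
        records = [_record(2 * i, "resting") for i in range(20)]
        clusters = bc.segment_clusters(fixes, 50)
        props = [bc.cluster_behaviour_coherence(records, clusters, m)["resting"]
                 for m in (12, 8, 4, 1)]
        assert all(b >= a for a, b in zip(props, props[1:]))


class TestGpsSpeed:
    def test_100m_in_50s_is_2ms(self):
        f1 = _fix(0, 52.0, 13.0)
        m_per_deg = np.radians(1) * EARTH_RADIUS_M * np.cos(np.radians(52.0))
        f2 = bc.GpsFix("a", T0 + pd.Timedelta(seconds=50), 52.0,
                       13.0 + 100.0 / m_per_deg)
        speeds = bc.gps_speed([f1, f2])
        assert speeds["speed"].iloc[0] == pytest.approx(2.0, rel=1e-3)

    def test_identical_coordinates_zero(self):
        speeds = bc.gps_speed([_fix(0, 52.0, 13.0), _fix(4, 52.0, 13.0)])
        assert speeds["speed"].iloc[0] == 0.0

    def test_duplicate_timestamp_raises(self):
        with pytest.raises(DegenerateIntervalError):
            bc.gps_speed([_fix(0, 52.0, 13.0), _fix(0, 52.1, 13.0)])


class TestMatchSpeed:
    def _track(self):
        return _fixes_at_meters(np.arange(6) * 100.0, step_min=4.0)

    def test_burst_5s_after_fix_matched(self):
        fixes = self._track()
        rec = _record(0, "walking")
        rec.burst_start = fixes[2].time + pd.Timedelta(seconds=5)
        matched = bc.match_speed_to_behaviour([rec], fixes)
        assert len(matched) == 1

    def test_boundary_10s_included(self):
        fixes = self._track()
        rec = _record(0, "walking")
        rec.burst_start = fixes[2].time + pd.Timedelta(seconds=10)
        assert len(bc.match_speed_to_behaviour([rec], fixes)) == 1

    def test_burst_11s_from_every_fix_unmatched(self):
        fixes = self._track()
        rec = _record(0, "walking")
        rec.burst_start = fixes[2].time + pd.Timedelta(seconds=11)
        assert len(bc.match_speed_to_behaviour([rec], fixes)) == 0

    def test_wilcoxon_detects_resting_slower_than_trotting(self, rng):
        # stationary first half, fast second half
        offsets = np.concatenate([np.zeros(60), np.arange(1, 61) * 600.0])
        fixes = _fixes_at_meters(offsets, step_min=4.0)
        records = ([_record(4 * i, "resting") for i in range(60)]
                   + [_record(4 * (60 + i), "trotting") for i in range(60)])
        matched = bc.match_speed_to_behaviour(records, fixes)
        assert len(matched) >= 100
        _, p = bc.speed_ranksum(matched)
        assert p < 0.01
        med = matched.groupby("behaviour")["speed"].median()
        assert med["resting"] < med["trotting"]


class TestDielComposition:
    def test_single_behaviour_everywhere(self):
        records = [_record(30 * i, "resting") for i in range(48)]
        table = bc.diel_composition(records)
        props = table.proportions()
        assert (props["resting"].dropna() == 1.0).all()

    def test_schedule_recovery_night_vs_day(self):
        records = []
        for d in range(16):
            for h in range(24):
                cls = "trotting" if (h < 6 or h >= 20) else "resting"
                records.append(_record(d * 1440 + h * 60 + 5, cls))
        table = bc.diel_composition(records, bin_minutes=60)
        props = table.proportions().groupby(level="bin").mean()
        night_bins = [b for b in props.index if b < 360 or b >= 1200]
        day_bins = [b for b in props.index if 360 <= b < 1200]
        assert props.loc[night_bins, "trotting"].mean() > 0.99
        assert props.loc[day_bins, "resting"].mean() > 0.99

    def test_short_month_flagged(self):
        records = [_record(1440 * d, "resting") for d in range(12)]
        table = bc.diel_composition(records)
        assert table.flagged_months == {"2023-03"}

    def test_full_month_not_flagged(self):
        mar1 = pd.Timestamp("2023-03-01T12:00:00Z")
        records = []
        for d in range(16):
            r = _record(0, "resting", bid=f"d{d}")
            r.burst_start = mar1 + pd.Timedelta(days=d)
            records.append(r)
        table = bc.diel_composition(records)
        assert not table.flagged_months


class TestActogram:
    def test_all_zero_values_blank_grid(self):
        times = [T0 + pd.Timedelta(minutes=30 * i) for i in range(48)]
        grid = bc.actogram(times, np.zeros(48))
        assert np.nansum(grid.values) == 0.0

    def test_nocturnal_signal_higher_at_night(self, rng):
        times, vals = [], []
        for d in range(3):
            for h in range(24):
                times.append(T0 + pd.Timedelta(days=d, hours=h))
                vals.append(1.0 if (h < 6 or h >= 20) else 0.05)
        grid = bc.actogram(times, vals, bin_minutes=60)
        night = np.nanmean(grid.values[:, list(range(6)) + list(range(20, 24))])
        day = np.nanmean(grid.values[:, 6:20])
        assert night > day

    def test_gap_days_preserved_as_blank_rows(self):
        times = [T0, T0 + pd.Timedelta(days=2)]
        grid = bc.actogram(times, [1.0, 1.0])
        assert len(grid.days) == 3
        assert np.all(np.isnan(grid.values[1]))

    def test_sun_events_attached(self):
        times = [T0 + pd.Timedelta(hours=h) for h in range(24)]
        grid = bc.actogram(times, np.ones(24), lat=52.52, lon=13.40)
        assert len(grid.sun_events) == len(grid.days)
        rise, sset = grid.sun_events[0]
        assert rise is not None and 0 < rise < sset < 1440


class TestSolar:
    def test_equator_equinox_near_six_and_eighteen(self):
        rise, sset = sunrise_sunset(date(2023, 3, 21), 0.0, 0.0)
        assert abs(rise.hour * 60 + rise.minute - 360) < 20
        assert abs(sset.hour * 60 + sset.minute - 1080) < 20

    def test_berlin_summer_long_day(self):
        rise, sset = sunrise_sunset(date(2023, 6, 21), 52.52, 13.40)
        daylight_h = (sset - rise).total_seconds() / 3600
        assert 16 < daylight_h < 17.5

    def test_polar_night_returns_none(self):
        rise, sset = sunrise_sunset(date(2023, 12, 21), 80.0, 0.0)
        assert rise is None and sset is None
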