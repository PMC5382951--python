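"""Haversine, path/straight-line stats, smoothing, activity bouts, sites."""

from datetime import date, datetime

import numpy as np
import pandas as pd
import pytest

from tuskrest import movement as mv
from tuskrest.timebase_io import load_table2, load_table3


KM_PER_DEG_LAT = 111.195  # 6371 km * pi/180


def track_frame(start, lats, lons):
    ts = pd.date_range(start, periods=len(lats), freq="1min")
    return pd.DataFrame({"timestamp": ts, "lat": lats, "lon": lons})


class TestHaversine:
    def test_identical_points_are_zero(self):
        assert mv.haversine(-18.1, 25.0, -18.1, 25.0) == 0.0

    def test_symmetry(self):
        d1 = mv.haversine(-18.1, 25.0, -17.9, 25.2)
        d2 = mv.haversine(-17.9, 25.2, -18.1, 25.0)
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_printed_site_pair_reproduced(self):
        # consecutive main-sleep sites on 15 -> 16 Apr, printed distance 2.77 km
        t3 = load_table3()
        m1 = t3[t3["animal"] == "M1"].set_index("rd")
        d = mv.haversine(m1.loc[2, "lat"], m1.loc[2, "lon"],
                         m1.loc[3, "lat"], m1.loc[3, "lon"])
        assert d == pytest.approx(2.77, abs=0.03)

    def test_agrees_with_planar_geometry_at_study_scale(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            lat0 = -18.0 + rng.uniform(-0.5, 0.5)
            lon0 = 25.0 + rng.uniform(-0.5, 0.5)
            dlat = rng.uniform(-0.2, 0.2)
            dlon = rng.uniform(-0.2, 0.2)
            planar = np.hypot(dlat * KM_PER_DEG_LAT,
                              dlon * KM_PER_DEG_LAT *
                              np.cos(np.radians(lat0 + dlat / 2)))
            hav = mv.haversine(lat0, lon0, lat0 + dlat, lon0 + dlon)
            assert hav == pytest.approx(planar, rel=5e-3)


class TestPathAndStraight:
    def test_right_angle_track(self):
        # 3 km north then 4 km east: path 7, endpoints 5
        lat0, lon0 = -18.0, 25.0
        lat1 = lat0 + 3.0 / KM_PER_DEG_LAT
        lon1 = lon0 + 4.0 / (KM_PER_DEG_LAT * np.cos(np.radians(lat1)))
        track = track_frame("2014-04-14 12:00", [lat0, lat1, lat1],
                            [lon0, lon0, lon1])
        seg = mv.path_and_straightline(track, datetime(2014, 4, 14, 12, 0),
                                       datetime(2014, 4, 14, 12, 2))
        assert seg.path_km == pytest.approx(7.0, rel=1e-3)
        assert seg.straight_km == pytest.approx(5.0, rel=1e-3)

    def test_collinear_track_path_equals_straight(self):
        lats = -18.0 + np.arange(30) * 0.001
        track = track_frame("2014-04-14 12:00", lats, np.full(30, 25.0))
        seg = mv.path_and_straightline(track, datetime(2014, 4, 14, 12, 0),
                                       datetime(2014, 4, 14, 12, 29))
        assert seg.path_km == pytest.approx(seg.straight_km, rel=1e-9)

    def test_random_walk_path_is_sum_of_steps_and_bounds_straight(self):
        rng = np.random.default_rng(9)
        steps_km = rng.uniform(0.01, 0.05, 120)
        heading = rng.uniform(0, 2 * np.pi, 120)
        lat = -18.0 + np.concatenate(
            [[0], np.cumsum(steps_km * np.cos(heading)) / KM_PER_DEG_LAT])
        lon = 25.0 + np.concatenate(
            [[0], np.cumsum(steps_km * np.sin(heading)) /
             (KM_PER_DEG_LAT * np.cos(np.radians(-18.0)))])
        track = track_frame("2014-04-14 12:00", lat, lon)
        seg = mv.path_and_straightline(track, track["timestamp"].iloc[0],
                                       track["timestamp"].iloc[-1])
        assert seg.path_km == pytest.approx(steps_km.sum(), rel=2e-3)
        assert seg.path_km >= seg.straight_km

    def test_gap_flagging(self):
        track = track_frame("2014-04-14 12:00", [-18.0, -18.001], [25.0, 25.0])
        track.loc[1, "timestamp"] += pd.Timedelta(minutes=45)
        seg = mv.path_and_straightline(track, datetime(2014, 4, 14, 12, 0),
                                       datetime(2014, 4, 14, 13, 0))
        assert seg.gap_flagged


class TestSpeedAndBouts:
    def test_stationary_track_all_zero(self):
        track = track_frame("2014-04-14 12:00", np.full(60, -18.0),
                            np.full(60, 25.0))
        sp = mv.moving_average(mv.speed_series(track))
        assert (sp == 0).all()

    def test_constant_speed_smoothed_flat(self):
        lats = -18.0 + np.arange(120) * (3.0 / 60) / KM_PER_DEG_LAT  # 3 km/h
        track = track_frame("2014-04-14 12:00", lats, np.full(120, 25.0))
        sp = mv.moving_average(mv.speed_series(track))
        assert sp.iloc[10:-10].to_numpy() == pytest.approx(3.0, rel=1e-3)

    def test_planted_bout_detected_with_correct_extent(self):
        n = 24 * 60
        speed_kmh = np.full(n, 0.3)
        speed_kmh[600:1200] = 3.0  # 10-h fast bout
        ts = pd.date_range("2014-04-14 12:00", periods=n, freq="1min")
        sp = mv.moving_average(pd.Series(speed_kmh, index=ts))
        bouts = mv.detect_activity_bouts(sp, speed_thresh_kmh=1.5,
                                         min_duration_min=120)
        assert len(bouts) == 1
        assert abs(bouts[0].duration_min - 600) <= 30

    def test_quiet_track_has_no_bouts(self):
        ts = pd.date_range("2014-04-14 12:00", periods=600, freq="1min")
        sp = pd.Series(0.4, index=ts)
        assert mv.detect_activity_bouts(sp) == []

    def test_two_separated_bouts(self):
        n = 24 * 60
        speed = np.full(n, 0.2)
        speed[120:330] = 3.0
        speed[510:720] = 3.0  # 3 h after the first ends
        ts = pd.date_range("2014-04-14 12:00", periods=n, freq="1min")
        bouts = mv.detect_activity_bouts(
            mv.moving_average(pd.Series(speed, index=ts)))
        assert len(bouts) == 2


class TestSleepSites:
    def test_same_coordinates_give_zero_between(self):
        sites = pd.DataFrame({"date": [date(2014, 4, 14)], "lat": [-18.1],
                              "lon": [25.0]})
        _, _, between = mv.sleep_site_distances(sites, sites.copy())
        assert between["distance_km"].iloc[0] == 0.0

    def test_printed_inter_animal_distance(self):
        t3 = load_table3()
        m1 = t3[t3["animal"] == "M1"][["date", "lat", "lon"]]
        m2 = t3[t3["animal"] == "M2"][["date", "lat", "lon"]]
        _, _, between = mv.sleep_site_distances(m1, m2)
        d = between.set_index("date").loc[date(2014, 4, 16), "distance_km"]
        assert d == pytest.approx(0.18, abs=0.03)

    def test_consecutive_distances_span_no_sleep_gaps(self):
        t3 = load_table3()
        m1 = t3[t3["animal"] == "M1"][["date", "lat", "lon"]]
        cons = mv.consecutive_site_distances(m1)
        row = cons.set_index("date").loc[date(2014, 4, 18)]
        assert row["from_date"] == date(2014, 4, 16)  # 17 Apr had no site
        assert row["distance_km"] == pytest.approx(29.26, abs=0.1)

    def test_between_skips_nights_where_either_missed(self):
        t2 = load_table2()
        t3 = load_table3()
        m1 = t3[t3["animal"] == "M1"][["date", "lat", "lon"]]
        m2 = t3[t3["animal"] == "M2"][["date", "lat", "lon"]]
        _, _, between = mv.sleep_site_distances(m1, m2)
        expected = t2.drop_duplicates("date")["dist_m1_m2_km"].notna().sum()
        assert len(between) == expected
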