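import dataclasses
import math

import numpy as np
import pytest

from timeact.geo import RoadNetwork, Track
from timeact.rulebased import (IN_VEHICLE, INDOOR, OUTDOOR_STATIC,
                               OUTDOOR_WALKING, UNTAGGED, MovingPeriod,
                               RuleConfig, StaticCluster, classify_static_cluster,
                               classify_track, classify_travel_mode,
                               consolidate_moving_periods, detect_home_clusters,
                               detect_static_clusters, refine_cluster_lines,
                               tag_moving_points)
from conftest import make_track

CFG = RuleConfig()


# ---------------------------------------------------------------- oracles

def brute_force_clusters(track, cfg=CFG):
    """Independent cluster oracle: maximal merge of every qualifying window."""
    n = len(track)
    member = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(i, n):
            if all(track.speed[k] < cfg.static_speed_max for k in range(i, j + 1)) \
                    and track.t[j] - track.t[i] >= cfg.static_min_duration:
                member[i:j + 1] = True
    out, start = [], None
    for i in range(n + 1):
        inside = i < n and member[i]
        if inside and start is None:
            start = i
        elif not inside and start is not None:
            out.append(list(range(start, i)))
            start = None
    return out


def brute_force_consolidate(moving, cfg=CFG):
    """Independent single-pass trace of the gap-absorption rule."""
    runs = []
    i = 0
    n = len(moving)
    while i < n:
        if moving[i]:
            j = i
            while j + 1 < n and moving[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    merged = []
    for run in runs:
        if merged:
            gap = run[0] - merged[-1][1] - 1
            need = max(2, gap)
            if gap >= 1 and (merged[-1][1] - merged[-1][0] + 1) >= need \
                    and (run[1] - run[0] + 1) >= need:
                merged[-1][1] = run[1]
                continue
        merged.append(run)
    return [list(range(a, b + 1)) for a, b in merged if b - a + 1 >= 2]


# ---------------------------------------------------------- static clusters

class TestDetectStaticClusters:
    def test_ten_minutes_of_zero_speed_is_one_cluster(self):
        tr = make_track(np.zeros(41))  # 40 intervals x 15 s = 10 min
        (c,) = detect_static_clusters(tr, CFG)
        assert c.members.size == 41

    def test_45s_slow_run_below_one_minute_is_untagged(self):
        speeds = [20, 20, 1, 1, 1, 1, 20, 20]  # slow span = 45 s < 60 s
        tr = make_track(speeds)
        assert detect_static_clusters(tr, CFG) == []

    def test_matches_brute_force_on_random_tracks(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            speeds = rng.choice([0.0, 1.0, 2.9, 3.0, 20.0], size=60)
            tr = make_track(speeds)
            got = [list(c.members) for c in detect_static_clusters(tr, CFG)]
            assert got == brute_force_clusters(tr, CFG)

    def test_empty_track_gives_empty_list(self):
        tr = Track(np.array([]), x=np.array([]), y=np.array([]), speed=np.array([]))
        assert detect_static_clusters(tr, CFG) == []

    def test_membership_monotone_in_speed_threshold(self):
        rng = np.random.default_rng(5)
        tr = make_track(rng.uniform(0, 6, 80))
        lo = {i for c in detect_static_clusters(tr, RuleConfig(static_speed_max=3.0))
              for i in c.members}
        hi = {i for c in detect_static_clusters(tr, RuleConfig(static_speed_max=5.0))
              for i in c.members}
        assert lo <= hi


class TestRefineClusterLines:
    def _cluster(self, tr):
        (c,) = detect_static_clusters(tr, CFG)
        return c

    def test_leading_collinear_march_removed(self):
        # first 6 points march in a straight line at 20 m spacing, then a
        # zigzag between two spots 20 m apart (detour 40 m per triple)
        n = 20
        x = np.concatenate([np.arange(6) * 20.0, np.full(n - 6, 150.0)])
        y = np.concatenate([np.zeros(6), [0.0 if i % 2 else 20.0 for i in range(n - 6)]])
        tr = Track(np.arange(n) * 15.0, x=x, y=y, speed=np.full(n, 1.0))
        refined = refine_cluster_lines(self._cluster(tr), tr, CFG)
        assert set(refined.line_excluded) == {0, 1, 2, 3, 4, 5}
        assert refined.members[0] == 6
        assert refined.members[-1] == n - 1  # trailing scan removed nothing

    def test_jitter_cloud_unchanged(self):
        # cycle of a wide triangle: every consecutive triple detours > 1 m
        n = 12
        tri = [(0.0, 0.0), (30.0, 0.0), (0.0, 30.0)]
        x = np.array([tri[i % 3][0] for i in range(n)])
        y = np.array([tri[i % 3][1] for i in range(n)])
        tr = Track(np.arange(n) * 15.0, x=x, y=y, speed=np.zeros(n))
        refined = refine_cluster_lines(self._cluster(tr), tr, CFG)
        assert refined.line_excluded.size == 0
        assert refined.members.size == n

    def test_repeated_identical_coordinate_scan_trace(self):
        # 8 identical points: forward scan eats triples 0-2 and 3-5, leaving
        # 6-7; a 15 s remainder is under one minute, so the cluster dissolves
        n = 8
        tr = Track(np.arange(n) * 15.0, x=np.full(n, 5.0), y=np.full(n, 5.0),
                   speed=np.zeros(n))
        refined = refine_cluster_lines(self._cluster(tr), tr, CFG)
        assert refined.dissolved
        assert refined.members.size == 0

    def test_two_point_cluster_returned_unchanged(self):
        c = StaticCluster(members=np.array([0, 1]))
        tr = make_track([0.0, 0.0])
        assert refine_cluster_lines(c, tr, CFG) is c


# ---------------------------------------------------------- moving points

class TestTagMovingPoints:
    def test_lone_fast_point_by_criterion_1(self):
        tr = make_track([1, 1, 40, 1, 1])
        moving, prov = tag_moving_points(tr, [], None, CFG)
        assert list(moving) == [False, False, True, False, False]
        assert prov[2] == "moving:speed>high"

    def test_bounded_gap_filled_by_criterion_2(self):
        tr = make_track([20, 1, 1, 1, 20])
        moving, prov = tag_moving_points(tr, [], None, CFG)
        assert moving.all()
        assert prov[2] == "moving:bounded_gap"

    def test_gap_longer_than_five_not_filled(self):
        tr = make_track([20, 1, 1, 1, 1, 1, 1, 20])  # 6-point gap
        moving, _ = tag_moving_points(tr, [], None, CFG)
        assert not moving[1:7].any()

    def test_sustained_walk_run_by_criterion_3(self):
        tr = make_track([1, 4, 4, 4, 4, 4, 4, 4, 1])
        moving, prov = tag_moving_points(tr, [], None, CFG)
        assert moving[1:8].all() and not moving[0] and not moving[8]
        assert prov[4] == "moving:sustained_run"

    def test_five_point_run_too_short_for_criterion_3(self):
        tr = make_track([1, 4, 4, 4, 4, 4, 1])
        moving, _ = tag_moving_points(tr, [], None, CFG)
        assert not moving.any()

    def test_on_road_far_from_clusters_by_criterion_4(self):
        n = 8
        tr = Track(np.arange(n) * 15.0, x=np.arange(n) * 10.0, y=np.full(n, 5.0),
                   speed=np.full(n, 1.0))
        roads = RoadNetwork.from_polylines([[(-1000, 0), (1000, 0)]])
        far_cluster = StaticCluster(members=np.array([], dtype=int))
        far_cluster.centroid = (5000.0, 5000.0)
        far_cluster.dissolved = False
        moving, prov = tag_moving_points(tr, [], roads, CFG)
        assert moving.all()
        assert set(prov) == {"moving:on_road"}

    def test_criterion_4_blocked_near_cluster_centre(self):
        n = 8
        tr = Track(np.arange(n) * 15.0, x=np.arange(n) * 2.0, y=np.full(n, 5.0),
                   speed=np.full(n, 1.0))
        roads = RoadNetwork.from_polylines([[(-1000, 0), (1000, 0)]])
        near = StaticCluster(members=np.array([], dtype=int))
        near.centroid = (7.0, 5.0)
        moving, _ = tag_moving_points(tr, [near], roads, CFG)
        assert not moving.any()  # all points within 25 m of the centroid

    def test_missing_roads_logs_and_skips_criterion_4(self, caplog):
        tr = make_track([1, 1, 1])
        with caplog.at_level("WARNING"):
            moving, _ = tag_moving_points(tr, [], None, CFG)
        assert "road" in caplog.text.lower()
        assert not moving.any()

    def test_residual_speed_by_criterion_5(self):
        tr = make_track([1, 12, 1])
        moving, prov = tag_moving_points(tr, [], None, CFG)
        assert moving[1] and prov[1] == "moving:residual_speed"

    def test_cluster_members_frozen(self):
        tr = make_track(np.concatenate([np.zeros(6), [40.0]]))
        clusters = detect_static_clusters(tr, CFG)
        moving, _ = tag_moving_points(tr, clusters, None, CFG)
        assert not moving[:6].any() and moving[6]


# ----------------------------------------------------------- consolidation

class TestConsolidation:
    def _periods(self, moving):
        tr = make_track(np.zeros(len(moving)))
        return [list(p.members) for p in
                consolidate_moving_periods(np.array(moving), tr, [], CFG)]

    def test_single_gap_two_flankers(self):
        assert self._periods([1, 1, 0, 1, 1]) == [[0, 1, 2, 3, 4]]

    def test_three_gap_three_flankers(self):
        assert self._periods([1, 1, 1, 0, 0, 0, 1, 1, 1]) == [list(range(9))]

    def test_single_flankers_stay_unmerged(self):
        # M U M: only one moving point each side; the 1-point runs are
        # dropped from the period list (residual handling)
        assert self._periods([1, 0, 1]) == []

    def test_matches_brute_force_trace(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            moving = rng.random(40) < 0.5
            assert self._periods(moving) == brute_force_consolidate(moving, CFG)

    def test_gap_containing_cluster_member_not_absorbed(self):
        moving = np.array([1, 1, 0, 1, 1], dtype=bool)
        tr = make_track(np.zeros(5))
        c = StaticCluster(members=np.array([2]))
        got = [list(p.members) for p in consolidate_moving_periods(moving, tr, [c], CFG)]
        assert got == [[0, 1], [3, 4]]


# ------------------------------------------------------------- travel mode

class TestTravelMode:
    @pytest.mark.parametrize("speeds,expected", [
        ([12, 11, 6, 6, 6], IN_VEHICLE),    # 2nd highest 11, median 6
        ([4, 5, 4, 5, 11], OUTDOOR_WALKING),  # 2nd highest 5
        ([10, 10, 10], OUTDOOR_WALKING),    # boundary: 10 is not above 10
        ([6, 6, 30], OUTDOOR_WALKING),      # median 6 > 5 but 2nd highest 6 < 10
        ([20, 20], IN_VEHICLE),
    ])
    def test_rule_evaluation(self, speeds, expected):
        tr = make_track(speeds)
        p = MovingPeriod(members=np.arange(len(speeds)))
        assert classify_travel_mode(p, tr, CFG) == expected

    def test_single_point_uses_its_own_speed_twice(self):
        tr = make_track([12.0])
        p = MovingPeriod(members=np.array([0]))
        assert classify_travel_mode(p, tr, CFG) == IN_VEHICLE

    def test_empty_period_raises(self):
        tr = make_track([1.0])
        with pytest.raises(ValueError):
            classify_travel_mode(MovingPeriod(members=np.array([], int)), tr, CFG)


# ------------------------------------------------------------------- home

def _cluster_at(t0, t1, centroid=(0.0, 0.0), n=10):
    c = StaticCluster(members=np.arange(n))
    c.t_start, c.t_end = float(t0), float(t1)
    c.centroid = centroid
    return c


class TestHomeDetection:
    def test_cluster_spanning_midnight_is_home(self):
        c = _cluster_at(-3600, 3600)  # 23:00 to 01:00 around epoch midnight
        (out,), home = detect_home_clusters([c], CFG)
        assert out.is_home and home == (0.0, 0.0)

    def test_daytime_cluster_not_home(self):
        c = _cluster_at(9 * 3600, 17 * 3600)
        (out,), home = detect_home_clusters([c], CFG)
        assert not out.is_home and home is None

    def test_thirty_hour_cluster_home_by_duration(self):
        c = _cluster_at(3600, 3600 + 30 * 3600)
        (out,), _ = detect_home_clusters([c], CFG)
        assert out.is_home

    def test_hint_overrides_detection(self):
        c = _cluster_at(9 * 3600, 10 * 3600)
        _, home = detect_home_clusters([c], CFG, home_hint=(5.0, 6.0))
        assert home == (5.0, 6.0)

    def test_timezone_offset_moves_midnight(self):
        cfg = dataclasses.replace(CFG, tz_offset_s=-8 * 3600.0)  # UTC-8
        c = _cluster_at(7 * 3600, 9 * 3600)  # 23:00-01:00 local
        (out,), _ = detect_home_clusters([c], cfg)
        assert out.is_home


# ---------------------------------------------------------- static cascade

def _stats_cluster(duration_s, centroid, second_lowest=0.0, rng_range=1.0,
                   jitter=1.0):
    c = StaticCluster(members=np.arange(4))
    c.t_start, c.t_end = 0.0, float(duration_s)
    c.centroid = centroid
    c.second_lowest_speed = second_lowest
    c.geographic_range = rng_range
    c.median_jitter = jitter
    return c


class TestStaticCascade:
    HOME = (0.0, 0.0)

    def test_three_hour_cluster_is_indoor_anywhere(self):
        c = _stats_cluster(3 * 3600, (900.0, 0.0))
        label, rule = classify_static_cluster(c, self.HOME, CFG)
        assert label == INDOOR and rule.endswith("R1_long_duration")

    def test_short_far_tight_cluster_is_outdoor(self):
        c = _stats_cluster(4 * 60, (500.0, 0.0), second_lowest=0.0, rng_range=3.0)
        label, rule = classify_static_cluster(c, self.HOME, CFG)
        assert label == OUTDOOR_STATIC and rule.endswith("R3_short_far_from_home")

    def test_cluster_at_home_is_indoor(self):
        c = _stats_cluster(20 * 60, (5.0, 0.0))
        label, rule = classify_static_cluster(c, self.HOME, CFG)
        assert label == INDOOR and rule.endswith("R2_at_home")

    def test_elevated_second_lowest_speed_is_indoor(self):
        c = _stats_cluster(20 * 60, (500.0, 0.0), second_lowest=0.5)
        label, rule = classify_static_cluster(c, self.HOME, CFG)
        assert label == INDOOR and rule.endswith("R4_second_lowest_speed")

    def test_wide_scatter_is_indoor(self):
        c = _stats_cluster(20 * 60, (500.0, 0.0), second_lowest=0.0,
                           rng_range=100.0, jitter=10.0)
        label, rule = classify_static_cluster(c, self.HOME, CFG)
        assert label == INDOOR and rule.endswith("R5_scatter")

    def test_default_outdoor_static(self):
        c = _stats_cluster(20 * 60, (500.0, 0.0), second_lowest=0.0,
                           rng_range=10.0, jitter=10.0)
        label, rule = classify_static_cluster(c, self.HOME, CFG)
        assert label == OUTDOOR_STATIC and rule.endswith("R6_default")

    def test_home_rules_skipped_without_home(self):
        c = _stats_cluster(4 * 60, (500.0, 0.0), second_lowest=0.5)
        label, rule = classify_static_cluster(c, None, CFG)
        assert label == INDOOR and rule.endswith("R4_second_lowest_speed")


# ------------------------------------------------------------- end to end

class TestClassifyTrack:
    def test_empty_track(self):
        tr = Track(np.array([]), x=np.array([]), y=np.array([]), speed=np.array([]))
        assert classify_track(tr) == []

    def test_all_static_midnight_track_is_indoor_home(self):
        rng = np.random.default_rng(9)
        n = 400  # 100 min around midnight
        t = -3000.0 + np.arange(n) * 15.0
        tr = Track(t, x=rng.normal(0, 3, n), y=rng.normal(0, 3, n),
                   speed=np.zeros(n))
        records = classify_track(tr)
        labels = {r.label for r in records}
        assert labels == {INDOOR}
        assert any("home" in r.rule_fired for r in records)

    def test_partition_every_point_labeled_once(self, low_noise_labels):
        gt, track, labels, records = low_noise_labels
        assert len(records) == len(track)
        assert sorted(r.index for r in records) == list(range(len(track)))
        assert UNTAGGED not in set(labels)
        assert all(r.rule_fired for r in records)

    def test_deterministic(self, low_noise_day):
        gt, track = low_noise_day
        a = [r.label for r in classify_track(track, gt.roads)]
        b = [r.label for r in classify_track(track, gt.roads)]
        assert a == b

    def test_low_noise_day_recovers_indoor_and_vehicle(self, low_noise_labels):
        gt, track, labels, _ = low_noise_labels
        for cls in (INDOOR, IN_VEHICLE):
            truth = gt.labels == cls
            assert np.mean(labels[truth] == cls) >= 0.95

    def test_mode_split_correct_on_noise_free_periods(self, low_noise_labels):
        # drives cruise at >= 30 km/h, walks at 3-6 km/h: every moving
        # period that overlaps a drive is in_vehicle, walks are walking
        gt, track, labels, records = low_noise_labels
        drive = gt.labels == IN_VEHICLE
        walk = gt.labels == OUTDOOR_WALKING
        moving_pred = np.isin(labels, [IN_VEHICLE, OUTDOOR_WALKING])
        assert np.mean(labels[drive & moving_pred] == IN_VEHICLE) == 1.0
        assert np.mean(labels[walk & moving_pred] == OUTDOOR_WALKING) == 1.0
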