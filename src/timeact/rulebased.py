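"""Multi-stage rule classifier for time-activity patterns.

The classifier labels every GPS fix with one of four categories — indoor,
outdoor static, outdoor walking, in-vehicle travel — through six stages:

1. static-cluster detection (sustained near-zero speed),
2. line refinement inside clusters (collinear fixes betray slow movement
   misfiled as a stop),
3. moving-point tagging by five ordered criteria (speed, bounded gaps,
   sustained walking-speed runs, road proximity, residual speed),
4. consolidation of moving runs across short untagged gaps,
5. travel-mode split of each moving period (walking vs in-vehicle) from its
   second-highest and median speed,
6. indoor/outdoor split of each static cluster by a rule cascade using
   duration, distance to the detected home, member speeds, and scatter.

Every threshold lives in :class:`RuleConfig`; every terminal label carries
the name of the rule that produced it.  The module is fully deterministic.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .geo import RoadNetwork, Track, distance_difference, planar_distance
from .tracks_io import LabelRecord

__all__ = [
    "INDOOR", "OUTDOOR_STATIC", "OUTDOOR_WALKING", "IN_VEHICLE", "UNTAGGED",
    "CLASS_ORDER", "RuleConfig", "StaticCluster", "MovingPeriod",
    "detect_static_clusters", "refine_cluster_lines", "tag_moving_points",
    "consolidate_moving_periods", "classify_travel_mode",
    "detect_home_clusters", "classify_static_cluster", "classify_track",
]

log = logging.getLogger(__name__)

INDOOR = "indoor"
OUTDOOR_STATIC = "outdoor_static"
OUTDOOR_WALKING = "outdoor_walking"
IN_VEHICLE = "in_vehicle"
UNTAGGED = "untagged"

#: fixed class order used everywhere (confusion matrices, tie-breaks)
CLASS_ORDER = (INDOOR, OUTDOOR_STATIC, OUTDOOR_WALKING, IN_VEHICLE)


@dataclass(frozen=True)
class RuleConfig:
    """Every numeric threshold of the rule classifier, overridable.

    Speeds in km/h, distances in metres, durations in seconds unless noted.
    Inequalities are strict on the side the rule text uses ("above",
    "lower than"): boundary values do not qualify.
    """

    static_speed_max: float = 3.0         # cluster membership: speed < this
    static_min_duration: float = 60.0     # s; minimum cluster time span
    line_tolerance: float = 1.0           # m; collinearity tolerance
    moving_speed_high: float = 15.0       # criterion 1: speed > this
    bounded_gap_max_points: int = 5       # criterion 2 gap length
    run_min_points: int = 6               # criterion 3 run length
    run_speed_min: float = 2.5            # criterion 3: speed > this
    road_buffer: float = 10.0             # criterion 4: within this of a road
    cluster_center_buffer: float = 25.0   # criterion 4: beyond this of centroids
    residual_moving_speed: float = 10.0   # criterion 5 / residual split
    vehicle_second_highest_speed: float = 10.0
    vehicle_median_speed: float = 5.0
    outdoor_max_duration: float = 2 * 3600.0   # R1: cluster longer -> indoor
    short_cluster_duration: float = 5 * 60.0   # R3: shorter + far from home
    home_min_duration: float = 24 * 3600.0     # home if cluster lasts longer
    home_indoor_radius: float = 10.0           # R2: within this of home
    apartment_radius: float = 50.0             # R3: beyond this of home
    indoor_second_lowest_speed: float = 0.1    # R4: 2nd-lowest speed > this
    scatter_factor: float = 2.0                # R5: range > factor x median jitter
    tz_offset_s: float = 0.0                   # local time = UTC + offset
    split_gap_min: float = 30.0                # min; dropout that splits a track

    def __post_init__(self):
        if not (self.run_speed_min < self.vehicle_median_speed
                < self.residual_moving_speed <= self.moving_speed_high):
            raise ValueError("speed thresholds must be ordered "
                             "run < vehicle-median < residual <= high")


@dataclass
class StaticCluster:
    """A contiguous low-speed episode (a stop), possibly line-refined."""

    members: np.ndarray                    # surviving member indices
    line_excluded: np.ndarray = field(default_factory=lambda: np.array([], int))
    dissolved: bool = False
    label: str = UNTAGGED
    rule_fired: str = ""
    is_home: bool = False
    cluster_id: int = -1

    # populated from the parent track
    t_start: float = math.nan
    t_end: float = math.nan
    centroid: tuple[float, float] = (math.nan, math.nan)
    second_lowest_speed: float = math.nan
    geographic_range: float = math.nan
    median_jitter: float = math.nan

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def refresh_stats(self, track: Track) -> None:
        m = self.members
        if m.size == 0:
            return
        self.t_start = float(track.t[m[0]])
        self.t_end = float(track.t[m[-1]])
        x, y = track.x[m], track.y[m]
        self.centroid = (float(x.mean()), float(y.mean()))
        s = np.sort(track.speed[m])
        self.second_lowest_speed = float(s[1] if s.size > 1 else s[0])
        self.geographic_range = _diameter(x, y)
        self.median_jitter = float(np.median(
            np.hypot(x - self.centroid[0], y - self.centroid[1])))

    @property
    def critical_points(self) -> tuple[int, int, int]:
        m = self.members
        return int(m[0]), int(m[m.size // 2]), int(m[-1])


@dataclass
class MovingPeriod:
    """A consolidated run of moving fixes, later split into a travel mode."""

    members: np.ndarray
    mode: str = UNTAGGED
    period_id: int = -1
    second_highest_speed: float = math.nan
    median_speed: float = math.nan


def _diameter(x: np.ndarray, y: np.ndarray) -> float:
    """Maximum pairwise distance (geographic range) of a point set."""
    if x.size <= 1:
        return 0.0
    pts = np.column_stack([x, y])
    if pts.shape[0] > 400:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            # degenerate (collinear/coincident): bbox diagonal is exact
            return float(math.hypot(x.max() - x.min(), y.max() - y.min()))
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def _runs(mask: np.ndarray, boundary: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] index runs of True values not crossing a boundary."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is not None and boundary[i]:
            runs.append((start, i - 1))
            start = i
        elif v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def _boundaries(track: Track, cfg: RuleConfig) -> np.ndarray:
    """True at i when a recording dropout separates i-1 from i."""
    b = np.zeros(len(track), dtype=bool)
    if len(track) >= 2:
        b[1:] = np.diff(track.t) > cfg.split_gap_min * 60.0
    return b


def detect_static_clusters(track: Track, cfg: RuleConfig = RuleConfig()) -> list[StaticCluster]:
    """Maximal low-speed runs spanning at least the minimum stop duration.

    Every member must have speed strictly below ``static_speed_max`` and the
    run's time span (last minus first timestamp, robust to interval jitter)
    must reach ``static_min_duration``.
    """
    if len(track) == 0:
        return []
    track.require_projected()
    slow = track.speed < cfg.static_speed_max
    clusters = []
    for a, b in _runs(slow, _boundaries(track, cfg)):
        if track.t[b] - track.t[a] >= cfg.static_min_duration:
            c = StaticCluster(members=np.arange(a, b + 1))
            c.refresh_stats(track)
            clusters.append(c)
    return clusters


def refine_cluster_lines(cluster: StaticCluster, track: Track,
                         cfg: RuleConfig = RuleConfig()) -> StaticCluster:
    """Strip collinear leading/trailing fixes from a cluster.

    Scanning forward from the first member and backward from the last, each
    consecutive member triple whose detour (distance difference) is within
    ``line_tolerance`` is judged a line — slow movement, not a stop — and
    excluded.  Each scan stops at the first non-line triple; excluded points
    are not reused within a scan.  If the surviving members span less than
    the minimum stop duration the cluster dissolves.
    """
    members = list(cluster.members)
    if len(members) < 3:
        return cluster
    excluded: list[int] = []

    def scan(order: list[int]) -> list[int]:
        i = 0
        while i + 2 < len(order):
            tri = [track.point(order[i + k]) for k in range(3)]
            if distance_difference(*tri) <= cfg.line_tolerance:
                excluded.extend(order[i:i + 3])
                i += 3
            else:
                break
        return order[i:]

    remaining = scan(members)
    remaining = scan(remaining[::-1])[::-1]

    out = replace(cluster)
    out.line_excluded = np.array(sorted(excluded), dtype=int)
    out.members = np.array(remaining, dtype=int)
    if (out.members.size == 0
            or track.t[out.members[-1]] - track.t[out.members[0]] < cfg.static_min_duration):
        out.dissolved = True
        out.line_excluded = np.array(sorted(set(excluded) | set(remaining)), int)
        out.members = np.array([], dtype=int)
    else:
        out.refresh_stats(track)
    return out


def tag_moving_points(track: Track, clusters: Sequence[StaticCluster],
                      roads: Optional[RoadNetwork],
                      cfg: RuleConfig = RuleConfig()) -> tuple[np.ndarray, np.ndarray]:
    """Flag moving fixes by five criteria applied in order.

    1. speed above ``moving_speed_high``;
    2. at most ``bounded_gap_max_points`` sequential untagged fixes bounded
       on both sides by criterion-1 moving fixes;
    3. at least ``run_min_points`` continuous fixes with speed above
       ``run_speed_min``;
    4. fixes within ``road_buffer`` of a roadway but beyond
       ``cluster_center_buffer`` of every static-cluster centroid;
    5. any remaining untagged fix with speed above ``residual_moving_speed``.

    Cluster members are frozen and ineligible.  Returns (moving flags,
    criterion provenance strings).
    """
    n = len(track)
    moving = np.zeros(n, dtype=bool)
    prov = np.full(n, "", dtype=object)
    in_cluster = np.zeros(n, dtype=bool)
    centroids = []
    for c in clusters:
        if not c.dissolved:
            in_cluster[c.members] = True
            centroids.append(c.centroid)
    eligible = ~in_cluster
    bnd = _boundaries(track, cfg)

    # 1 — high speed
    c1 = eligible & (track.speed > cfg.moving_speed_high)
    moving |= c1
    prov[c1 & (prov == "")] = "moving:speed>high"

    # 2 — short untagged gap bounded by two criterion-1 moving points
    for a, b in _runs(eligible & ~moving, bnd):
        npts = b - a + 1
        if npts <= cfg.bounded_gap_max_points:
            if a - 1 >= 0 and b + 1 < n and c1[a - 1] and c1[b + 1] \
                    and not bnd[a] and not bnd[b + 1]:
                moving[a:b + 1] = True
                prov[a:b + 1] = "moving:bounded_gap"

    # 3 — sustained run above walking threshold
    fast = eligible & (track.speed > cfg.run_speed_min)
    for a, b in _runs(fast, bnd):
        if b - a + 1 >= cfg.run_min_points:
            new = np.arange(a, b + 1)[~moving[a:b + 1]]
            moving[new] = True
            prov[new] = "moving:sustained_run"

    # 4 — on a road, away from every cluster centre
    if roads is None or len(roads) == 0:
        log.warning("no road network supplied; road-proximity criterion skipped")
    else:
        cand = np.flatnonzero(eligible & ~moving)
        if cand.size:
            dists = roads.distances(track.x[cand], track.y[cand])
            near_road = dists <= cfg.road_buffer
            if centroids:
                cx = np.array([c[0] for c in centroids])
                cy = np.array([c[1] for c in centroids])
                dc = np.hypot(track.x[cand, None] - cx[None, :],
                              track.y[cand, None] - cy[None, :]).min(axis=1)
                far_from_clusters = dc > cfg.cluster_center_buffer
            else:
                far_from_clusters = np.ones(cand.size, dtype=bool)
            hit = cand[near_road & far_from_clusters]
            moving[hit] = True
            prov[hit] = "moving:on_road"

    # 5 — residual speed
    c5 = eligible & ~moving & (track.speed > cfg.residual_moving_speed)
    moving[c5] = True
    prov[c5] = "moving:residual_speed"
    return moving, prov


def consolidate_moving_periods(moving: np.ndarray, track: Track,
                               clusters: Sequence[StaticCluster] = (),
                               cfg: RuleConfig = RuleConfig()) -> list[MovingPeriod]:
    """Merge moving runs across short untagged gaps into periods.

    A gap of n untagged fixes (n >= 1, no cluster members inside) is
    absorbed when at least max(2, n) continuous moving fixes flank it on
    each side; the merge proceeds left to right in a single pass.  Runs
    that end up with fewer than 2 points are returned to the untagged pool
    rather than becoming periods.
    """
    n = len(track)
    in_cluster = np.zeros(n, dtype=bool)
    for c in clusters:
        if not c.dissolved:
            in_cluster[c.members] = True
    bnd = _boundaries(track, cfg)

    runs = _runs(moving, bnd)
    merged: list[list[int]] = []
    for a, b in runs:
        if merged:
            pa, pb = merged[-1]
            gap = a - pb - 1
            gap_ok = (gap >= 1
                      and not in_cluster[pb + 1:a].any()
                      and not bnd[pb + 1:a + 1].any()
                      and (pb - pa + 1) >= max(2, gap)
                      and (b - a + 1) >= max(2, gap))
            if gap_ok:
                merged[-1] = [pa, b]
                continue
        merged.append([a, b])

    periods = []
    for a, b in merged:
        if b - a + 1 >= 2:
            periods.append(MovingPeriod(members=np.arange(a, b + 1)))
    return periods


def classify_travel_mode(period: MovingPeriod, track: Track,
                         cfg: RuleConfig = RuleConfig()) -> str:
    """Walking vs in-vehicle from the period's speed distribution.

    In-vehicle requires the second-highest speed strictly above 10 km/h AND
    the median strictly above 5 km/h; otherwise walking.  A single-point
    period uses its one speed for both statistics.
    """
    speeds = track.speed[period.members]
    if speeds.size == 0:
        raise ValueError("empty moving period")
    second_highest = float(np.sort(speeds)[-2] if speeds.size > 1 else speeds[0])
    median = float(np.median(speeds))
    period.second_highest_speed = second_highest
    period.median_speed = median
    if (second_highest > cfg.vehicle_second_highest_speed
            and median > cfg.vehicle_median_speed):
        return IN_VEHICLE
    return OUTDOOR_WALKING


def detect_home_clusters(clusters: Sequence[StaticCluster],
                         cfg: RuleConfig = RuleConfig(),
                         home_hint: Optional[tuple[float, float]] = None,
                         ) -> tuple[list[StaticCluster], Optional[tuple[float, float]]]:
    """Flag home clusters and locate home.

    A cluster is home when its local-time span contains midnight or it lasts
    longer than ``home_min_duration`` — people are overwhelmingly at home at
    12:00 AM.  Home = member-count-weighted centroid of home clusters; an
    explicit ``home_hint`` overrides detection.
    """
    wsum = np.zeros(2)
    wtot = 0
    for c in clusters:
        if c.dissolved:
            continue
        t0 = c.t_start + cfg.tz_offset_s
        t1 = c.t_end + cfg.tz_offset_s
        contains_midnight = math.floor(t1 / 86400.0) >= math.ceil(t0 / 86400.0)
        if contains_midnight or c.duration > cfg.home_min_duration:
            c.is_home = True
            wsum += np.array(c.centroid) * c.members.size
            wtot += c.members.size
    if home_hint is not None:
        return list(clusters), (float(home_hint[0]), float(home_hint[1]))
    if wtot == 0:
        log.warning("no home cluster detected and no hint given; "
                    "home-distance rules will be skipped")
        return list(clusters), None
    return list(clusters), (float(wsum[0] / wtot), float(wsum[1] / wtot))


def classify_static_cluster(cluster: StaticCluster,
                            home: Optional[tuple[float, float]],
                            cfg: RuleConfig = RuleConfig()) -> tuple[str, str]:
    """Indoor vs outdoor static, by an ordered cascade of evidence.

    R1 very long stops are indoor (almost all outdoor stops end within two
    hours); R2 stops at the home location are indoor (GPS accuracy ~10 m);
    R3 short stops far from home are outdoor; R4 elevated second-lowest
    speed marks the multipath scatter of an indoor fix; R5 wide geographic
    range relative to the cluster's own jitter likewise; R6 otherwise
    outdoor static.  Home-distance rules are skipped when home is unknown.
    """
    if cluster.duration > cfg.outdoor_max_duration:
        return INDOOR, "static:R1_long_duration"
    if home is not None:
        d_home = planar_distance(cluster.centroid, home)
        if d_home <= cfg.home_indoor_radius:
            return INDOOR, "static:R2_at_home"
        if d_home > cfg.apartment_radius and cluster.duration < cfg.short_cluster_duration:
            return OUTDOOR_STATIC, "static:R3_short_far_from_home"
    if cluster.second_lowest_speed > cfg.indoor_second_lowest_speed:
        return INDOOR, "static:R4_second_lowest_speed"
    if cluster.geographic_range > cfg.scatter_factor * cluster.median_jitter:
        return INDOOR, "static:R5_scatter"
    return OUTDOOR_STATIC, "static:R6_default"


def classify_track(track: Track, roads: Optional[RoadNetwork] = None,
                   cfg: RuleConfig = RuleConfig(),
                   home_hint: Optional[tuple[float, float]] = None,
                   ) -> list[LabelRecord]:
    """Run the full rule pipeline; one terminal label per point.

    Residual untagged points (dissolved clusters, unmerged short runs) are
    labeled outdoor static when slow (below ``residual_moving_speed``),
    otherwise they inherit the label of the temporally nearest labeled
    neighbour.
    """
    n = len(track)
    if n == 0:
        return []
    track.require_projected()
    if track.speed is None:
        from .preprocess import derive_speed
        track = derive_speed(track)

    clusters = [refine_cluster_lines(c, track, cfg)
                for c in detect_static_clusters(track, cfg)]
    moving, mov_prov = tag_moving_points(track, clusters, roads, cfg)
    periods = consolidate_moving_periods(moving, track, clusters, cfg)
    clusters, home = detect_home_clusters(clusters, cfg, home_hint)

    label = np.full(n, UNTAGGED, dtype=object)
    prov = np.full(n, "", dtype=object)
    segid = np.full(n, -1, dtype=int)

    cid = 0
    for c in clusters:
        if c.dissolved:
            continue
        c.cluster_id = cid
        c.label, c.rule_fired = classify_static_cluster(c, home, cfg)
        label[c.members] = c.label
        prov[c.members] = c.rule_fired + (":home" if c.is_home else "")
        segid[c.members] = cid
        cid += 1

    pid = cid
    for p in periods:
        p.period_id = pid
        p.mode = classify_travel_mode(p, track, cfg)
        label[p.members] = p.mode
        mode_tag = "mode:" + ("vehicle" if p.mode == IN_VEHICLE else "walking")
        for i in p.members:
            prov[i] = (mov_prov[i] or "moving:consolidated") + ";" + mode_tag
        segid[p.members] = pid
        pid += 1

    # residuals
    labeled_idx = np.flatnonzero(label != UNTAGGED)
    for i in np.flatnonzero(label == UNTAGGED):
        if track.speed[i] < cfg.residual_moving_speed or labeled_idx.size == 0:
            label[i] = OUTDOOR_STATIC
            prov[i] = "residual:slow"
        else:
            j = labeled_idx[np.argmin(np.abs(track.t[labeled_idx] - track.t[i]))]
            label[i] = label[j]
            prov[i] = "residual:attached"
            segid[i] = segid[j]

    return [LabelRecord(index=i, timestamp=float(track.t[i]), label=str(label[i]),
                        segment_id=int(segid[i]), rule_fired=str(prov[i]))
            for i in range(n)]
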