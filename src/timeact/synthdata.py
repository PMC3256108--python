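"""Ground-truth GPS trajectory simulator.

Generates labeled person-days that emulate interval-logged GPS tracking
under free-living conditions: a nominal 15-second recording interval with
occasional jitter, indoor dwells whose fixes scatter with small Gaussian
jitter plus a heavy multipath tail (errors up to ~300 m) and signal
dropouts, outdoor stops with tight jitter, walks at 3-6 km/h with short
stops, and on-road drives along an orthogonal grid network at 30-70 km/h
cruise speeds with optional idling.  Device speed is the true kinematic
speed with multiplicative noise and rare >200 km/h glitch spikes, so the
speed-correction cleaning rule has something to fire on.

Every scenario is deterministic under its seed; the per-point true activity
labels make every pipeline stage testable without field data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .geo import RoadNetwork, Track
from .rulebased import (IN_VEHICLE, INDOOR, OUTDOOR_STATIC, OUTDOOR_WALKING)

__all__ = ["ScheduleBlock", "SimConfig", "GroundTruthTrack", "make_road_grid",
           "simulate_day", "emit_fixture_suite", "scenario_config", "SCENARIOS"]


@dataclass(frozen=True)
class ScheduleBlock:
    """One schedule entry: an activity, its duration, and a destination.

    ``location`` names an anchor in :attr:`SimConfig.anchors`; ``None``
    means "stay where you are" (used by in-vehicle idle blocks).
    """

    activity: str
    duration_min: float
    location: str | None = None


#: default commuter-day schedule; durations sum to 24 h.  Drives depart from
#: dwells or stops (boarding pauses), as in real commutes, so moving periods
#: of different modes are separated by stationary episodes.
DEFAULT_SCHEDULE = (
    ScheduleBlock("indoor", 425, "home"),
    ScheduleBlock("outdoor_static", 2, "yard"),      # boarding the car
    ScheduleBlock("in_vehicle", 8, "work"),
    ScheduleBlock("indoor", 307, "work"),
    ScheduleBlock("outdoor_walking", 30, "park"),
    ScheduleBlock("outdoor_static", 45, "park"),
    ScheduleBlock("outdoor_walking", 30, "work"),
    ScheduleBlock("indoor", 185, "work"),
    ScheduleBlock("outdoor_static", 2, "work_lot"),  # boarding the car
    ScheduleBlock("in_vehicle", 8, "yard"),
    ScheduleBlock("outdoor_static", 45, "yard"),
    ScheduleBlock("outdoor_walking", 35, "home"),
    ScheduleBlock("indoor", 318, "home"),
)

DEFAULT_ANCHORS = {
    "home": (120.0, 260.0),
    "corner": (160.0, 380.0),
    "work": (2620.0, 2380.0),
    "work_lot": (2680.0, 2330.0),
    "park": (2120.0, 2180.0),
    "yard": (80.0, 210.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated person-day."""

    seed: int
    interval_s: float = 15.0
    interval_jitter_prob: float = 0.02   # gap becomes 14 or 16 s
    schedule: tuple = DEFAULT_SCHEDULE
    anchors: dict = field(default_factory=lambda: dict(DEFAULT_ANCHORS))
    extent_m: float = 3000.0
    road_spacing_m: float = 500.0
    # positional noise
    indoor_jitter_m: float = 5.0
    indoor_heavy_tail_prob: float = 0.02
    indoor_heavy_tail_max_m: float = 300.0
    indoor_dropout_prob: float = 0.05
    outdoor_jitter_m: float = 3.0
    # movement regimes
    walk_speed_range: tuple = (3.0, 6.0)     # km/h
    walk_stop_prob: float = 0.05             # per interval
    drive_cruise_range: tuple = (30.0, 70.0)  # km/h
    drive_end_idle_s: float = 15.0
    # device-speed noise
    speed_noise_frac: float = 0.10
    speed_spike_prob: float = 0.0005         # rare >200 km/h artifacts
    # tracks start at 21:00 local the previous evening so that local midnight
    # falls strictly inside the overnight home dwell, as in multi-day tracking
    day_start_epoch_s: float = -10800.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for p in (self.interval_jitter_prob, self.indoor_heavy_tail_prob,
                  self.indoor_dropout_prob, self.walk_stop_prob,
                  self.speed_spike_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for b in self.schedule:
            if b.duration_min <= 0:
                raise ValueError("schedule durations must be positive")


@dataclass
class GroundTruthTrack:
    """Simulated track plus the per-point truth the models try to recover."""

    track: Track
    labels: np.ndarray        # true activity per point
    block_ids: np.ndarray     # schedule-block index per point
    roads: RoadNetwork
    config: SimConfig


def make_road_grid(extent_m: float, spacing_m: float) -> RoadNetwork:
    """Orthogonal grid of road centerlines covering [0, extent]^2."""
    if not extent_m > spacing_m > 0:
        raise ValueError("need extent > spacing > 0")
    ticks = np.arange(0.0, extent_m + spacing_m / 2, spacing_m)
    polylines = [[(0.0, t), (extent_m, t)] for t in ticks]
    polylines += [[(t, 0.0), (t, extent_m)] for t in ticks]
    return RoadNetwork.from_polylines(polylines)


def _snap(v: float, spacing: float) -> float:
    return round(v / spacing) * spacing


def _route(start: tuple, end: tuple, spacing: float) -> list[tuple]:
    """L-shaped on-road route between two off-road points.

    Board at the start snapped to its nearest horizontal road, travel along
    that road to the vertical road nearest the destination, then along it,
    then along the destination's horizontal road; alight at the point on
    that road nearest the destination.
    """
    sx, sy = start
    ex, ey = end
    y0 = _snap(sy, spacing)
    y1 = _snap(ey, spacing)
    xv = _snap(ex, spacing)
    pts = [(sx, y0), (xv, y0), (xv, y1), (ex, y1)]
    out = [pts[0]]
    for p in pts[1:]:
        if p != out[-1]:
            out.append(p)
    return out


def _walk_positions(rng, start, dest, n, dt, cfg: SimConfig):
    """Waypoint walking at sampled walk speeds with random short stops."""
    lo, hi = cfg.walk_speed_range
    pos = np.array(start, float)
    target = np.array(dest, float)
    xs, spd = [], []
    stopped = 0
    for _ in range(n):
        if stopped > 0:
            stopped -= 1
            v = 0.0
        elif rng.random() < cfg.walk_stop_prob:
            stopped = int(rng.integers(1, 4))
            v = 0.0
        else:
            v = rng.uniform(lo, hi)
            step = v / 3.6 * dt
            delta = target - pos
            dist = float(np.hypot(*delta))
            if dist < step:
                pos = target.copy()
                # meander near the destination once reached
                ang = rng.uniform(0, 2 * math.pi)
                r = rng.uniform(20.0, 80.0)
                target = np.array(dest) + r * np.array([math.cos(ang), math.sin(ang)])
            else:
                pos = pos + delta / dist * step
        xs.append(pos.copy())
        spd.append(v)
    return np.array(xs), np.array(spd)


def _drive_positions(rng, start, dest, n, dt, cfg: SimConfig):
    """On-road drive: idle, cruise along the L-route, idle out the block."""
    route = _route(start, dest, cfg.road_spacing_m)
    legs = [np.array(a, float) for a in route]
    seg_len = [float(np.hypot(*(legs[i + 1] - legs[i]))) for i in range(len(legs) - 1)]
    total = sum(seg_len)
    idle_pts = int(round(cfg.drive_end_idle_s / dt))
    move_n = max(n - 2 * idle_pts, 1)
    lo, hi = cfg.drive_cruise_range
    cruise = min(max(total / (move_n * dt) * 3.6, lo), hi)

    xs, spd = [], []
    for _ in range(idle_pts):
        xs.append(legs[0].copy())
        spd.append(0.0)
    s = 0.0
    for _ in range(move_n):
        s = min(s + cruise / 3.6 * dt, total)
        # locate distance s along the route
        rem = s
        pos = legs[-1].copy()
        for i, L in enumerate(seg_len):
            if rem <= L or i == len(seg_len) - 1:
                frac = 0.0 if L == 0 else min(rem / L, 1.0)
                pos = legs[i] + frac * (legs[i + 1] - legs[i])
                break
            rem -= L
        xs.append(pos)
        spd.append(cruise if s < total else 0.0)
    while len(xs) < n:
        xs.append(xs[-1].copy())
        spd.append(0.0)
    return np.array(xs[:n]), np.array(spd[:n])


def simulate_day(cfg: SimConfig) -> GroundTruthTrack:
    """Generate one labeled person-day under the configured conditions."""
    rng = np.random.default_rng(cfg.seed)
    roads = make_road_grid(cfg.extent_m, cfg.road_spacing_m)

    # timestamps for the whole day, with occasional interval jitter
    total_s = sum(b.duration_min for b in cfg.schedule) * 60.0
    times = [0.0]
    while times[-1] < total_s:
        gap = cfg.interval_s
        if rng.random() < cfg.interval_jitter_prob:
            gap += rng.choice([-1.0, 1.0])
        times.append(times[-1] + gap)
    t = np.array(times[:-1] if times[-1] >= total_s else times)

    # block membership
    edges = np.cumsum([0.0] + [b.duration_min * 60.0 for b in cfg.schedule])
    block_of = np.searchsorted(edges, t, side="right") - 1
    block_of = np.clip(block_of, 0, len(cfg.schedule) - 1)

    n = t.size
    true_xy = np.zeros((n, 2))
    true_speed = np.zeros(n)
    labels = np.empty(n, dtype=object)
    indoor_mask = np.zeros(n, dtype=bool)

    current = np.array(cfg.anchors[cfg.schedule[0].location
                                   if cfg.schedule[0].location else "home"], float)
    for bi, block in enumerate(cfg.schedule):
        idx = np.flatnonzero(block_of == bi)
        if idx.size == 0:
            continue
        dt = cfg.interval_s
        dest = (np.array(cfg.anchors[block.location], float)
                if block.location is not None else current.copy())
        act = block.activity
        if act == "indoor":
            true_xy[idx] = dest
            true_speed[idx] = 0.0
            labels[idx] = INDOOR
            indoor_mask[idx] = True
            current = dest
        elif act == "outdoor_static":
            true_xy[idx] = dest
            true_speed[idx] = 0.0
            labels[idx] = OUTDOOR_STATIC
            current = dest
        elif act == "outdoor_walking":
            xs, v = _walk_positions(rng, current, dest, idx.size, dt, cfg)
            true_xy[idx] = xs
            true_speed[idx] = v
            labels[idx] = OUTDOOR_WALKING
            current = xs[-1]
        elif act == "in_vehicle":
            xs, v = _drive_positions(rng, current, dest, idx.size, dt, cfg)
            true_xy[idx] = xs
            true_speed[idx] = v
            labels[idx] = IN_VEHICLE
            current = xs[-1]
        elif act == "in_vehicle_idle":
            true_xy[idx] = current
            true_speed[idx] = 0.0
            labels[idx] = IN_VEHICLE
        else:
            raise ValueError(f"unknown schedule activity {act!r}")

    # positional noise
    xy = true_xy + rng.normal(0.0, cfg.outdoor_jitter_m, size=(n, 2))
    ind = np.flatnonzero(indoor_mask)
    if ind.size:
        xy[ind] = true_xy[ind] + rng.normal(0.0, cfg.indoor_jitter_m, size=(ind.size, 2))
        tail = ind[rng.random(ind.size) < cfg.indoor_heavy_tail_prob]
        if tail.size:
            r = rng.uniform(0.0, cfg.indoor_heavy_tail_max_m, size=tail.size)
            ang = rng.uniform(0.0, 2 * math.pi, size=tail.size)
            xy[tail] = true_xy[tail] + np.column_stack([r * np.cos(ang), r * np.sin(ang)])

    # device speed: kinematic truth, multiplicative noise, rare spikes
    speed = np.clip(true_speed * (1.0 + rng.normal(0.0, cfg.speed_noise_frac, n)), 0.0, None)
    spikes = rng.random(n) < cfg.speed_spike_prob
    speed[spikes] = rng.uniform(220.0, 900.0, size=int(spikes.sum()))

    # indoor dropouts
    keep = np.ones(n, dtype=bool)
    if ind.size:
        keep[ind] = rng.random(ind.size) >= cfg.indoor_dropout_prob

    sel = np.flatnonzero(keep)
    track = Track(t[sel] + cfg.day_start_epoch_s, x=xy[sel, 0], y=xy[sel, 1],
                  speed=speed[sel], subject_id=f"sim{cfg.seed}")
    return GroundTruthTrack(track=track, labels=labels[sel],
                            block_ids=block_of[sel], roads=roads, config=cfg)


def _low_noise(seed: int, schedule=DEFAULT_SCHEDULE) -> SimConfig:
    return SimConfig(seed=seed, schedule=schedule, interval_jitter_prob=0.0,
                     indoor_jitter_m=2.0, indoor_heavy_tail_prob=0.0,
                     indoor_dropout_prob=0.0, outdoor_jitter_m=2.0,
                     walk_stop_prob=0.02, drive_end_idle_s=0.0,
                     speed_noise_frac=0.02, speed_spike_prob=0.0)


IDLE_SCHEDULE = (
    ScheduleBlock("indoor", 430, "home"),
    ScheduleBlock("outdoor_static", 2, "yard"),      # boarding the car
    ScheduleBlock("in_vehicle", 8, "work"),
    ScheduleBlock("indoor", 505, "work"),
    ScheduleBlock("in_vehicle", 4, "midroad"),
    ScheduleBlock("in_vehicle_idle", 4, None),       # waiting at the curb
    ScheduleBlock("in_vehicle", 5, "yard"),
    ScheduleBlock("outdoor_static", 2, "yard"),
    ScheduleBlock("outdoor_walking", 18, "home"),
    ScheduleBlock("indoor", 462, "home"),
)

WALK_HEAVY_SCHEDULE = (
    ScheduleBlock("indoor", 420, "home"),
    ScheduleBlock("outdoor_walking", 60, "park"),
    ScheduleBlock("outdoor_static", 30, "park"),
    ScheduleBlock("outdoor_walking", 60, "work"),
    ScheduleBlock("indoor", 300, "work"),
    ScheduleBlock("outdoor_walking", 90, "corner"),
    ScheduleBlock("outdoor_static", 30, "yard"),
    ScheduleBlock("outdoor_walking", 30, "home"),
    ScheduleBlock("indoor", 420, "home"),
)


def scenario_config(name: str, seed: int) -> SimConfig:
    """Named study scenarios used throughout the tests."""
    if name == "commuter":
        return SimConfig(seed=seed)
    if name == "commuter_low_noise":
        return _low_noise(seed)
    if name == "commuter_idle":
        cfg = _low_noise(seed, schedule=IDLE_SCHEDULE)
        anchors = dict(DEFAULT_ANCHORS)
        anchors["midroad"] = (2500.0, 980.0)  # alights on the x=2500 road
        return replace(cfg, anchors=anchors)
    if name == "walk_heavy":
        return SimConfig(seed=seed, schedule=WALK_HEAVY_SCHEDULE)
    if name == "noisy_indoor":
        return SimConfig(seed=seed, indoor_heavy_tail_prob=0.10,
                         indoor_dropout_prob=0.15, indoor_jitter_m=15.0)
    raise ValueError(f"unknown scenario {name!r}")


SCENARIOS = ("commuter", "commuter_low_noise", "commuter_idle",
             "walk_heavy", "noisy_indoor")


def emit_fixture_suite(out_dir, seed: int = 7) -> list[Path]:
    """Write the canonical scenario fixtures as CSV + GeoJSON, seeded.

    Re-emission with the same arguments is byte-identical.
    """
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in SCENARIOS:
        cfg = scenario_config(name, seed)
        gt = simulate_day(cfg)
        path = out_dir / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write("subject_id,timestamp,x,y,speed_kmh,true_label,block_id\n")
            tr = gt.track
            for i in range(len(tr)):
                ts = np.datetime64(int(round(tr.t[i] * 1000)), "ms")
                fh.write(f"{tr.subject_id},{ts}Z,{tr.x[i]:.3f},{tr.y[i]:.3f},"
                         f"{tr.speed[i]:.3f},{gt.labels[i]},{gt.block_ids[i]}\n")
        written.append(path)

    # degenerate fixtures: single point and all-static day
    deg = out_dir / "degenerate_single_point.csv"
    with open(deg, "w") as fh:
        fh.write("subject_id,timestamp,x,y,speed_kmh\n")
        fh.write("deg,1970-01-01T12:00:00Z,100.000,100.000,0.000\n")
    written.append(deg)

    cfg = scenario_config("commuter_low_noise", seed)
    static_cfg = replace(cfg, schedule=(ScheduleBlock("indoor", 1440, "home"),))
    gt = simulate_day(static_cfg)
    path = out_dir / "degenerate_all_static.csv"
    with open(path, "w") as fh:
        fh.write("subject_id,timestamp,x,y,speed_kmh,true_label,block_id\n")
        tr = gt.track
        for i in range(len(tr)):
            ts = np.datetime64(int(round(tr.t[i] * 1000)), "ms")
            fh.write(f"{tr.subject_id},{ts}Z,{tr.x[i]:.3f},{tr.y[i]:.3f},"
                     f"{tr.speed[i]:.3f},{gt.labels[i]},{gt.block_ids[i]}\n")
    written.append(path)

    roads = make_road_grid(SimConfig(seed=seed).extent_m,
                           SimConfig(seed=seed).road_spacing_m)
    features = []
    for seg in roads.segments:
        features.append({
            "type": "Feature", "properties": {},
            "geometry": {"type": "LineString",
                         "coordinates": [[float(x), float(y)] for x, y in seg.coords]},
        })
    roads_path = out_dir / "roads.geojson"
    with open(roads_path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features},
                  fh, sort_keys=True, separators=(",", ":"))
    written.append(roads_path)
    return written
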