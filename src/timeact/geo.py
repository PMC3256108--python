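"""Geometric primitives: planar projection, distances, and road networks.

All classification rules operate on planar coordinates in metres.  Field
data arrive as geodetic latitude/longitude and are projected to UTM
(NAD83 / GRS80); synthetic fixtures are generated directly in planar metres
and bypass projection via :attr:`ProjectionSpec.planar`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point
from shapely.strtree import STRtree

from . import _utm

__all__ = [
    "GeoPoint",
    "Track",
    "ProjectionSpec",
    "RoadNetwork",
    "ProjectionError",
    "project_track",
    "planar_distance",
    "distance_difference",
    "distance_ratio",
    "distance_to_nearest_road",
]


class ProjectionError(ValueError):
    """Raised when an operation needs planar coordinates that are absent."""


class GeoPoint(NamedTuple):
    """A single GPS fix. ``x``/``y`` are planar metres once projected."""

    timestamp: float  # seconds since epoch
    x: float = math.nan
    y: float = math.nan
    speed: float = math.nan  # km/h
    lat: float = math.nan
    lon: float = math.nan
    subject_id: str = ""


@dataclass
class Track:
    """A time-ordered sequence of GPS fixes for one subject, as columns.

    Invariants (enforced by :func:`timeact.preprocess.clean_track`):
    timestamps strictly increasing, speeds non-negative, x/y finite once
    projected.
    """

    t: np.ndarray                      # epoch seconds
    x: np.ndarray = field(default=None)  # planar metres
    y: np.ndarray = field(default=None)
    speed: np.ndarray = field(default=None)  # km/h
    lat: np.ndarray = field(default=None)
    lon: np.ndarray = field(default=None)
    subject_id: str = "subject"
    speed_is_derived: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        n = self.t.size
        for name in ("x", "y", "speed", "lat", "lon"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.size != n:
                    raise ValueError(f"column {name!r} has length {v.size}, expected {n}")
                setattr(self, name, v)

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def is_projected(self) -> bool:
        return self.x is not None and self.y is not None

    def require_projected(self) -> None:
        if not self.is_projected:
            raise ProjectionError("track has no planar coordinates; project it first")

    def take(self, idx) -> "Track":
        idx = np.asarray(idx)
        cols = {
            name: (getattr(self, name)[idx] if getattr(self, name) is not None else None)
            for name in ("x", "y", "speed", "lat", "lon")
        }
        return Track(self.t[idx], subject_id=self.subject_id,
                     speed_is_derived=self.speed_is_derived, **cols)

    def point(self, i: int) -> GeoPoint:
        def _get(col):
            v = getattr(self, col)
            return float(v[i]) if v is not None else math.nan

        return GeoPoint(float(self.t[i]), _get("x"), _get("y"), _get("speed"),
                        _get("lat"), _get("lon"), self.subject_id)

    def points(self) -> Iterable[GeoPoint]:
        return (self.point(i) for i in range(len(self)))

    def to_dataframe(self) -> pd.DataFrame:
        data = {"subject_id": self.subject_id, "timestamp": self.t}
        for name in ("lat", "lon", "x", "y"):
            if getattr(self, name) is not None:
                data[name] = getattr(self, name)
        if self.speed is not None:
            data["speed_kmh"] = self.speed
        return pd.DataFrame(data)

    @classmethod
    def from_arrays(cls, t, x=None, y=None, speed=None, lat=None, lon=None,
                    subject_id="subject", speed_is_derived=False) -> "Track":
        return cls(np.asarray(t, float), x=x, y=y, speed=speed, lat=lat, lon=lon,
                   subject_id=subject_id, speed_is_derived=speed_is_derived)


@dataclass(frozen=True)
class ProjectionSpec:
    """Projection used for a study region.

    The study default is UTM zone 11N on NAD83.  ``planar=True`` marks
    inputs that are already in planar metres (synthetic fixtures) and makes
    :func:`project_track` a pass-through.
    """

    datum: str = "NAD83"
    zone: int = 11
    hemisphere: str = "N"
    planar: bool = False

    def forward(self, lat, lon):
        return _utm.geographic_to_utm(lat, lon, self.zone, self.hemisphere)

    def inverse(self, x, y):
        return _utm.utm_to_geographic(x, y, self.zone, self.hemisphere)


def project_track(track: Track, spec: ProjectionSpec) -> tuple[Track, list[tuple[int, str]]]:
    """Populate planar ``x``/``y`` on a lat/lon track.

    Returns the projected track and a list of ``(index, reason)`` for points
    rejected because their coordinates are out of range; rejected points are
    dropped from the returned track.
    """
    if spec.planar:
        track.require_projected()
        return track, []
    if track.lat is None or track.lon is None:
        raise ProjectionError("track has no lat/lon to project")

    bad_lat = ~(np.abs(track.lat) <= 90.0)
    bad_lon = ~(np.abs(track.lon) <= 180.0)
    rejects = [(int(i), "latitude out of range") for i in np.flatnonzero(bad_lat)]
    rejects += [(int(i), "longitude out of range")
                for i in np.flatnonzero(bad_lon & ~bad_lat)]
    keep = ~(bad_lat | bad_lon)
    kept = track.take(np.flatnonzero(keep))
    x, y = spec.forward(kept.lat, kept.lon)
    kept.x, kept.y = np.asarray(x, float), np.asarray(y, float)
    return kept, sorted(rejects)


def _xy(p) -> tuple[float, float]:
    if isinstance(p, GeoPoint):
        x, y = p.x, p.y
    else:
        x, y = p
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ProjectionError("point has no finite planar coordinates")
    return float(x), float(y)


def planar_distance(a, b) -> float:
    """Euclidean distance in metres between two projected points."""
    ax, ay = _xy(a)
    bx, by = _xy(b)
    return math.hypot(ax - bx, ay - by)


def distance_difference(p1, p2, p3) -> float:
    """Detour of the middle point: (d12 + d23) - d13, in metres.

    Zero exactly when the middle fix lies on the segment between its
    neighbours — the signature of straight-line movement; non-negative by
    the triangle inequality.
    """
    return planar_distance(p1, p2) + planar_distance(p2, p3) - planar_distance(p1, p3)


def distance_ratio(xs: Sequence[float] | np.ndarray, ys: np.ndarray | None = None) -> float:
    """Net displacement over path length for a series of fixes, in [0, 1].

    Accepts either a sequence of points/(x, y) pairs or two coordinate
    arrays.  A zero-length path (all fixes coincident) is defined as 1.
    """
    if ys is None:
        pts = [_xy(p) for p in xs]
        if len(pts) < 2:
            raise ValueError("distance_ratio needs at least 2 points")
        arr = np.asarray(pts, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    else:
        x = np.asarray(xs, float)
        y = np.asarray(ys, float)
        if x.size < 2:
            raise ValueError("distance_ratio needs at least 2 points")
    steps = np.hypot(np.diff(x), np.diff(y))
    path = float(steps.sum())
    if path == 0.0:
        return 1.0
    net = math.hypot(x[-1] - x[0], y[-1] - y[0])
    return min(net / path, 1.0)


class RoadNetwork:
    """Planar road centerlines with a spatial index for distance queries."""

    def __init__(self, segments: Sequence[LineString]):
        segs = []
        for g in segments:
            if g.geom_type == "MultiLineString":
                segs.extend(g.geoms)
            elif g.geom_type == "LineString":
                segs.append(g)
            else:
                raise ValueError(f"unsupported geometry {g.geom_type}")
        for g in segs:
            if not np.all(np.isfinite(np.asarray(g.coords))):
                raise ValueError("road segment has non-finite vertices")
        self.segments: list[LineString] = segs
        self._tree = STRtree(segs) if segs else None

    def __len__(self) -> int:
        return len(self.segments)

    @classmethod
    def from_polylines(cls, polylines: Iterable[Sequence[tuple[float, float]]]) -> "RoadNetwork":
        return cls([LineString(p) for p in polylines])

    def nearest_distance(self, x: float, y: float) -> float:
        if not self.segments:
            raise ValueError("empty road network")
        p = Point(x, y)
        i = self._tree.nearest(p)
        return float(self.segments[i].distance(p))

    def distances(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return np.array([self.nearest_distance(xi, yi) for xi, yi in zip(x, y)])


def distance_to_nearest_road(p, roads: RoadNetwork) -> float:
    """Minimum distance in metres from a projected point to the network."""
    x, y = _xy(p)
    return roads.nearest_distance(x, y)
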