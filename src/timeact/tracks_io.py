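"""Reading and writing tracks, labels, and road networks.

Formats
-------
* Track CSV: ``subject_id,timestamp,lat,lon[,speed_kmh][,label]`` with ISO 8601
  timestamps (UTC offset explicit).  Synthetic planar fixtures use ``x,y``
  columns instead of ``lat,lon``.
* GPX 1.1 track points with ``<time>`` elements.
* Roads: GeoJSON FeatureCollection of LineString / MultiLineString.
* Label CSV: the input columns plus ``label,segment_id,rule_fired``.

Malformed rows are never silently dropped: readers return a reject report
alongside the parsed points.  The one mandatory field is the timestamp —
points without one cannot be ordered and are excluded, mirroring standard
practice for interval-logged GPS data.
"""
from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import shape

from .geo import ProjectionSpec, RoadNetwork, Track

__all__ = [
    "LabelRecord",
    "RejectReport",
    "read_track",
    "write_labels",
    "read_labels",
    "read_roads",
]


@dataclass
class LabelRecord:
    """Terminal label assignment for one input point, with provenance."""

    index: int
    timestamp: float
    label: str
    segment_id: int = -1
    rule_fired: str = ""


@dataclass
class RejectReport:
    """Rows a reader could not use, with one reason per row."""

    rows: list[tuple[int, str]] = field(default_factory=list)

    def add(self, row: int, reason: str) -> None:
        self.rows.append((row, reason))

    def __len__(self) -> int:
        return len(self.rows)


class TrackFormatError(ValueError):
    pass


class EmptyTrackError(ValueError):
    pass


def read_track(path, fmt: str | None = None) -> tuple[Track, RejectReport]:
    """Read a track from CSV or GPX; returns (time-sorted track, rejects)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "gpx" if path.suffix.lower() == ".gpx" else "csv"
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "gpx":
        return _read_gpx(path)
    raise TrackFormatError(f"unknown track format {fmt!r}")


def _finish(df: pd.DataFrame, rejects: RejectReport, planar: bool,
            subject_id: str) -> tuple[Track, RejectReport]:
    df = df.sort_values("t", kind="stable").reset_index(drop=True)
    if len(df) == 0:
        raise EmptyTrackError("no valid points in input")
    kw = {}
    if planar:
        kw["x"], kw["y"] = df["x"].to_numpy(), df["y"].to_numpy()
    else:
        kw["lat"], kw["lon"] = df["lat"].to_numpy(), df["lon"].to_numpy()
    if "speed" in df:
        kw["speed"] = df["speed"].to_numpy()
    return Track(df["t"].to_numpy(), subject_id=subject_id, **kw), rejects


def _read_csv(path: Path) -> tuple[Track, RejectReport]:
    try:
        raw = pd.read_csv(path, dtype=str)
    except Exception as exc:  # noqa: BLE001
        raise TrackFormatError(f"cannot parse {path}: {exc}") from exc
    cols = {c.strip().lower(): c for c in raw.columns}
    planar = "x" in cols and "y" in cols
    if "timestamp" not in cols:
        raise TrackFormatError("CSV lacks a 'timestamp' column")
    if not planar and not ("lat" in cols and "lon" in cols):
        raise TrackFormatError("CSV needs lat/lon or x/y columns")

    rejects = RejectReport()
    ts = pd.to_datetime(raw[cols["timestamp"]], errors="coerce", utc=True)
    coord_a = pd.to_numeric(raw[cols["x" if planar else "lat"]], errors="coerce")
    coord_b = pd.to_numeric(raw[cols["y" if planar else "lon"]], errors="coerce")
    speed = (pd.to_numeric(raw[cols["speed_kmh"]], errors="coerce")
             if "speed_kmh" in cols else None)

    ok = ts.notna() & coord_a.notna() & coord_b.notna()
    for i in np.flatnonzero(ts.isna()):
        rejects.add(int(i), "missing or unparseable timestamp")
    for i in np.flatnonzero(ts.notna() & (coord_a.isna() | coord_b.isna())):
        rejects.add(int(i), "missing coordinate")

    subject = "subject"
    if "subject_id" in cols:
        vals = raw[cols["subject_id"]].dropna().unique()
        if len(vals):
            subject = str(vals[0])

    df = pd.DataFrame({
        "t": ts[ok].astype("int64") / 1e9,
        ("x" if planar else "lat"): coord_a[ok],
        ("y" if planar else "lon"): coord_b[ok],
    })
    if speed is not None:
        df["speed"] = speed[ok]
    return _finish(df, rejects, planar, subject)


_GPX_NS = "{http://www.topografix.com/GPX/1/1}"


def _read_gpx(path: Path) -> tuple[Track, RejectReport]:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise TrackFormatError(f"cannot parse {path}: {exc}") from exc
    rejects = RejectReport()
    rows = []
    for i, pt in enumerate(root.iter(f"{_GPX_NS}trkpt")):
        time_el = pt.find(f"{_GPX_NS}time")
        if time_el is None or not time_el.text:
            rejects.add(i, "missing or unparseable timestamp")
            continue
        t = pd.to_datetime(time_el.text, errors="coerce", utc=True)
        if pd.isna(t):
            rejects.add(i, "missing or unparseable timestamp")
            continue
        try:
            lat, lon = float(pt.get("lat")), float(pt.get("lon"))
        except (TypeError, ValueError):
            rejects.add(i, "missing coordinate")
            continue
        speed_el = pt.find(f"{_GPX_NS}speed")
        speed = float(speed_el.text) * 3.6 if speed_el is not None else np.nan
        rows.append({"t": t.value / 1e9, "lat": lat, "lon": lon, "speed": speed})
    df = pd.DataFrame(rows, columns=["t", "lat", "lon", "speed"])
    if df["speed"].isna().all():
        df = df.drop(columns=["speed"])
    return _finish(df, rejects, planar=False, subject_id=path.stem)


def write_labels(track: Track, labels: list[LabelRecord], path) -> None:
    """Write the labeled track as CSV; lossless under :func:`read_labels`."""
    if len(labels) != len(track):
        raise ValueError(f"{len(labels)} labels for {len(track)} points")
    df = track.to_dataframe()
    order = sorted(range(len(labels)), key=lambda i: labels[i].index)
    df["label"] = [labels[i].label for i in order]
    df["segment_id"] = [labels[i].segment_id for i in order]
    df["rule_fired"] = [labels[i].rule_fired for i in order]
    df["timestamp"] = [f"{t:.3f}" for t in df["timestamp"]]
    for col in ("lat", "lon", "x", "y", "speed_kmh"):
        if col in df:
            df[col] = [f"{v:.6f}" for v in df[col]]
    df.to_csv(path, index=False)


def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "timestamp" in df:
        try:
            df["timestamp"] = pd.to_numeric(df["timestamp"])
        except (ValueError, TypeError):  # ISO 8601 strings
            df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True) \
                                .astype("int64") / 1e9
    for col in ("lat", "lon", "x", "y", "speed_kmh"):
        if col in df:
            df[col] = pd.to_numeric(df[col])
    return df


def read_roads(path, projection: ProjectionSpec | None = None) -> RoadNetwork:
    """Read a GeoJSON FeatureCollection of road centerlines.

    Coordinates are taken as planar metres unless a non-planar
    ``projection`` is supplied, in which case they are treated as lon/lat
    and projected.
    """
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj.get("features", []) if gj.get("type") == "FeatureCollection" else [gj]
    geoms = []
    for f in feats:
        geom = shape(f["geometry"] if "geometry" in f else f)
        if projection is not None and not projection.planar:
            parts = geom.geoms if geom.geom_type == "MultiLineString" else [geom]
            from shapely.geometry import LineString
            projected = []
            for part in parts:
                lon, lat = np.asarray(part.coords).T
                x, y = projection.forward(lat, lon)
                projected.append(LineString(np.column_stack([x, y])))
            geoms.extend(projected)
        else:
            geoms.append(geom)
    return RoadNetwork(geoms)
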