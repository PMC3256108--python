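"""Windowed kinematic features for the forest classifier.

Each GPS fix gets summary statistics of speed, distance difference and
distance ratio over time windows centered on it (window membership is by
timestamp, robust to recording-interval jitter), plus point-to-point
acceleration.  The five predictors retained by the published selection
procedure — maximum speed in 4 and 60 minutes, median speed in 30 minutes,
maximum distance difference in 6 and 30 minutes — are the default feature
set; the full grid feeds the selection procedure itself.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import Track

__all__ = ["FeatureSpec", "FeatureMatrix", "FULL_WINDOWS_MIN", "FINAL5",
           "acceleration", "windowed_stats", "window_distance_ratio",
           "build_feature_matrix"]

#: window grid in minutes for the full feature set (spans 2-60 min)
FULL_WINDOWS_MIN = (2, 4, 6, 10, 15, 20, 30, 45, 60)

#: the five predictors of the final model, in importance order
FINAL5 = ("speed_max_4min", "speed_max_60min", "speed_median_30min",
          "dd_max_6min", "dd_max_30min")


@dataclass(frozen=True)
class FeatureSpec:
    """Which windows and statistics to compute.

    ``windows_min`` are centered window lengths in minutes; speed and
    distance difference get min/median/max (sd additionally for distance
    difference), each window gets a distance ratio, and acceleration is a
    single windowless column.
    """

    windows_min: tuple = FULL_WINDOWS_MIN
    include_acceleration: bool = True
    include_distance_ratio: bool = True
    only: tuple | None = None   # restrict to these column names

    @classmethod
    def final5(cls) -> "FeatureSpec":
        return cls(windows_min=(4, 6, 30, 60), include_acceleration=False,
                   include_distance_ratio=False, only=FINAL5)

    def column_names(self) -> list[str]:
        cols = []
        for w in self.windows_min:
            for stat in ("min", "median", "max"):
                cols.append(f"speed_{stat}_{w}min")
            for stat in ("min", "median", "max", "sd"):
                cols.append(f"dd_{stat}_{w}min")
            if self.include_distance_ratio:
                cols.append(f"dratio_{w}min")
        if self.include_acceleration:
            cols.append("acceleration")
        if self.only is not None:
            cols = [c for c in cols if c in self.only]
            cols.sort(key=lambda c: self.only.index(c))
        return cols


@dataclass
class FeatureMatrix:
    """Per-point feature values with validity and edge-truncation masks."""

    values: pd.DataFrame
    valid: pd.DataFrame          # False where a feature is undefined
    truncated: pd.Series         # window clipped by a track edge somewhere

    def __len__(self) -> int:
        return len(self.values)


def acceleration(track: Track) -> np.ndarray:
    """Speed change from the previous fix, km/h per interval; NaN at index 0."""
    v = track.speed
    out = np.full(len(track), np.nan)
    if len(track) >= 2:
        out[1:] = np.diff(v)
    return out


def _distance_differences(track: Track) -> tuple[np.ndarray, np.ndarray]:
    """Detour values for every consecutive triple, stamped at the middle fix."""
    track.require_projected()
    n = len(track)
    if n < 3:
        return np.array([]), np.array([])
    x, y = track.x, track.y
    d12 = np.hypot(x[1:-1] - x[:-2], y[1:-1] - y[:-2])
    d23 = np.hypot(x[2:] - x[1:-1], y[2:] - y[1:-1])
    d13 = np.hypot(x[2:] - x[:-2], y[2:] - y[:-2])
    return track.t[1:-1], d12 + d23 - d13


def _window_bounds(sample_t: np.ndarray, focal_t: np.ndarray,
                   half_window: float) -> tuple[np.ndarray, np.ndarray]:
    lo = np.searchsorted(sample_t, focal_t - half_window, side="left")
    hi = np.searchsorted(sample_t, focal_t + half_window, side="right")
    return lo, hi


def windowed_stats(track: Track, window_minutes: float,
                   quantity: str = "speed") -> dict[str, np.ndarray]:
    """Per-point min/median/max (and sd for distance difference) over a
    centered time window.

    Statistics run over all samples whose timestamps fall within half a
    window of the focal point's timestamp; truncated windows at the track
    edges use whatever samples are available and are flagged.
    """
    if quantity == "speed":
        st, sv = track.t, track.speed
        want_sd = False
    elif quantity == "distance_difference":
        st, sv = _distance_differences(track)
        want_sd = True
    else:
        raise ValueError(f"unknown quantity {quantity!r}")

    n = len(track)
    half = window_minutes * 60.0 / 2.0
    out = {k: np.full(n, np.nan) for k in
           (("min", "median", "max", "sd") if want_sd else ("min", "median", "max"))}
    out["truncated"] = np.zeros(n, dtype=bool)
    if n == 0:
        return out
    out["truncated"] = ((track.t - half < track.t[0]) | (track.t + half > track.t[-1]))
    if st.size == 0:
        return out
    lo, hi = _window_bounds(st, track.t, half)
    for i in range(n):
        vals = sv[lo[i]:hi[i]]
        if vals.size == 0:
            continue
        out["min"][i] = vals.min()
        out["max"][i] = vals.max()
        out["median"][i] = np.median(vals)
        if want_sd:
            out["sd"][i] = vals.std(ddof=1) if vals.size > 1 else np.nan
    return out


def window_distance_ratio(track: Track, window_minutes: float) -> np.ndarray:
    """Net displacement over path length within each centered window.

    1 for straight monotone motion and for a zero-length path; near 0 for
    jitter around a fixed location.
    """
    track.require_projected()
    n = len(track)
    out = np.full(n, np.nan)
    if n == 0:
        return out
    half = window_minutes * 60.0 / 2.0
    lo, hi = _window_bounds(track.t, track.t, half)
    x, y = track.x, track.y
    steps = np.concatenate([[0.0], np.hypot(np.diff(x), np.diff(y))])
    cum = np.cumsum(steps)
    for i in range(n):
        a, b = lo[i], hi[i] - 1
        if b <= a:
            out[i] = 1.0
            continue
        path = cum[b] - cum[a]
        if path == 0.0:
            out[i] = 1.0
        else:
            out[i] = min(np.hypot(x[b] - x[a], y[b] - y[a]) / path, 1.0)
    return out


def build_feature_matrix(track: Track, spec: FeatureSpec | str = "final5") -> FeatureMatrix:
    """Compute the feature matrix for a cleaned track.

    ``spec`` may be a :class:`FeatureSpec`, ``"final5"`` (the five selected
    predictors) or ``"full"`` (the whole window/statistic grid used by
    feature selection).
    """
    if isinstance(spec, str):
        spec = FeatureSpec.final5() if spec == "final5" else FeatureSpec()
    if track.speed is None:
        raise ValueError("track has no speeds; clean/derive speed first")

    cols = spec.column_names()
    n = len(track)
    values = pd.DataFrame(index=np.arange(n), columns=cols, dtype=float)
    truncated = np.zeros(n, dtype=bool)

    cache: dict[tuple, dict] = {}

    def stats_for(quantity: str, w: float) -> dict:
        key = (quantity, w)
        if key not in cache:
            cache[key] = windowed_stats(track, w, quantity)
        return cache[key]

    for col in cols:
        if col == "acceleration":
            values[col] = acceleration(track)
            continue
        prefix, stat, wname = col.split("_") if col.count("_") == 2 else (None, None, None)
        if prefix is None:  # dratio_<w>min
            prefix, wname = col.split("_")
            w = float(wname[:-3])
            values[col] = window_distance_ratio(track, w)
            truncated |= (track.t - w * 30.0 < track.t[0]) | (track.t + w * 30.0 > track.t[-1])
            continue
        w = float(wname[:-3])
        quantity = "speed" if prefix == "speed" else "distance_difference"
        s = stats_for(quantity, w)
        values[col] = s[stat]
        truncated |= s["truncated"]

    valid = values.notna()
    return FeatureMatrix(values=values, valid=valid, truncated=pd.Series(truncated))
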