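"""Data cleaning and recording-interval profiling.

Cleaning implements the study protocol for interval-logged GPS devices:
points without a timestamp are excluded (they cannot be ordered), device
speeds above a 200 km/h plausibility ceiling are corrected to zero
(satellite glitches that teleport the fix), and subjects whose recording
interval collapsed to 1 s for the majority of the track are flagged for
exclusion.  Positions are never relocated or smoothed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geo import Track

__all__ = ["CleaningReport", "clean_track", "derive_speed", "interval_profile",
           "split_on_gaps"]

log = logging.getLogger(__name__)

#: inter-point gap buckets in seconds: 1 s, 2-14 s, the nominal 15 s, > 15 s
INTERVAL_BUCKETS = ("1s", "2-14s", "15s", ">15s")


@dataclass
class CleaningReport:
    n_input: int = 0
    n_dropped_no_timestamp: int = 0
    n_dropped_duplicate_timestamp: int = 0
    n_speed_corrected: int = 0
    interval_shares: dict = field(default_factory=dict)
    exclude_subject: bool = False
    exclusion_reason: str = ""


def clean_track(track: Track, max_speed: float = 200.0) -> tuple[Track, CleaningReport]:
    """Apply timestamp and speed plausibility rules; idempotent.

    Points with NaN timestamps are dropped and counted; duplicate timestamps
    keep the first occurrence; speeds above ``max_speed`` km/h are set to 0
    with the point retained in place; negative or NaN speeds become 0.
    """
    report = CleaningReport(n_input=len(track))

    valid = np.isfinite(track.t)
    report.n_dropped_no_timestamp = int((~valid).sum())
    track = track.take(np.flatnonzero(valid))

    order = np.argsort(track.t, kind="stable")
    track = track.take(order)
    if len(track):
        keep = np.concatenate([[True], np.diff(track.t) > 0])
        report.n_dropped_duplicate_timestamp = int((~keep).sum())
        if report.n_dropped_duplicate_timestamp:
            log.warning("dropped %d duplicate-timestamp points",
                        report.n_dropped_duplicate_timestamp)
        track = track.take(np.flatnonzero(keep))

    if track.speed is not None and len(track):
        speed = track.speed.copy()
        spikes = speed > max_speed
        report.n_speed_corrected = int(spikes.sum())
        speed[spikes] = 0.0
        speed[~np.isfinite(speed) | (speed < 0)] = 0.0
        track.speed = speed
    return track, report


def derive_speed(track: Track) -> Track:
    """Fill speed from consecutive displacement over elapsed time, in km/h.

    The first point inherits the second point's value.  The track is marked
    ``speed_is_derived`` so downstream reports can distinguish device speed
    from this fallback.
    """
    track.require_projected()
    n = len(track)
    speed = np.zeros(n)
    if n >= 2:
        d = np.hypot(np.diff(track.x), np.diff(track.y))
        dt = np.diff(track.t)
        speed[1:] = d / dt * 3.6
        speed[0] = speed[1]
    out = track.take(np.arange(n))
    out.speed = speed
    out.speed_is_derived = True
    return out


def interval_profile(track: Track, majority_interval_s: float = 1.0) -> CleaningReport:
    """Histogram of inter-point gaps and the 1-second-majority exclusion flag.

    Gaps are bucketed at 1 s / 2-14 s / 15 s / > 15 s (integer-second
    resolution).  A subject with strictly more than 50% of gaps at
    ``majority_interval_s`` or shorter is flagged for exclusion: such a
    device was not logging at the nominal interval and would distort
    duration-based rules.
    """
    report = CleaningReport(n_input=len(track))
    if len(track) < 2:
        report.interval_shares = {b: 0.0 for b in INTERVAL_BUCKETS}
        return report
    gaps = np.rint(np.diff(track.t))
    shares = {
        "1s": float(np.mean(gaps <= 1)),
        "2-14s": float(np.mean((gaps >= 2) & (gaps <= 14))),
        "15s": float(np.mean(gaps == 15)),
        ">15s": float(np.mean(gaps > 15)),
    }
    report.interval_shares = shares
    if np.mean(gaps <= majority_interval_s) > 0.5:
        report.exclude_subject = True
        report.exclusion_reason = (
            "majority of recording intervals at or below "
            f"{majority_interval_s:g} s")
    return report


def split_on_gaps(track: Track, max_gap_min: float = 30.0) -> list[Track]:
    """Split a track into independent segments at dropouts longer than
    ``max_gap_min`` minutes, so signal loss cannot fabricate movement."""
    if len(track) < 2:
        return [track]
    breaks = np.flatnonzero(np.diff(track.t) > max_gap_min * 60.0) + 1
    if breaks.size == 0:
        return [track]
    pieces = []
    start = 0
    for b in list(breaks) + [len(track)]:
        pieces.append(track.take(np.arange(start, b)))
        start = b
    return pieces
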