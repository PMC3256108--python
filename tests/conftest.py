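import numpy as np
import pytest

from timeact.geo import Track
from timeact.preprocess import clean_track
from timeact.rulebased import classify_track
from timeact.synthdata import scenario_config, simulate_day


def make_track(speeds, interval=15.0, x=None, y=None, t0=0.0, subject="t"):
    """Planar test track from a speed sequence (km/h) at a fixed interval."""
    speeds = np.asarray(speeds, dtype=float)
    n = speeds.size
    t = t0 + np.arange(n) * interval
    if x is None:
        # positions consistent with the speeds along the x axis
        step = speeds / 3.6 * interval
        x = np.concatenate([[0.0], np.cumsum(step[1:])])
    if y is None:
        y = np.zeros(n)
    return Track(t, x=np.asarray(x, float), y=np.asarray(y, float),
                 speed=speeds, subject_id=subject)


@pytest.fixture(scope="session")
def low_noise_day():
    gt = simulate_day(scenario_config("commuter_low_noise", 1))
    track, _ = clean_track(gt.track)
    return gt, track


@pytest.fixture(scope="session")
def low_noise_labels(low_noise_day):
    gt, track = low_noise_day
    records = classify_track(track, gt.roads)
    return gt, track, np.array([r.label for r in records]), records


@pytest.fixture(scope="session")
def noisy_day():
    gt = simulate_day(scenario_config("commuter", 7))
    track, _ = clean_track(gt.track)
    return gt, track
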