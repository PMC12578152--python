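import numpy as np
import pandas as pd
import pytest

from pigpen_mot.simulate import preset, simulate_pen
from pigpen_mot.tracker import Tracker, TrackerConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_box_tuple(rng, span=100.0):
    """Random valid (cx, cy, w, h) tuple."""
    return (
        float(rng.uniform(-span, span)),
        float(rng.uniform(-span, span)),
        float(rng.uniform(0.5, span / 2)),
        float(rng.uniform(0.5, span / 2)),
    )


def track_to_dataframe(results):
    """Flatten Tracker.run output into an evaluation-ready DataFrame."""
    rows = [
        (frame, r.track_id, *r.box.to_tlwh())
        for frame, outs in results.items()
        for r in outs
    ]
    return pd.DataFrame(rows, columns=["frame", "id", "left", "top", "w", "h"])


def run_tracker(scene, mode="improved"):
    cfg = TrackerConfig() if mode == "improved" else TrackerConfig.baseline()
    return track_to_dataframe(Tracker(cfg).run(scene.detections))


@pytest.fixture(scope="session")
def small_scene():
    """A short sparse daytime scene reused by several test modules."""
    return simulate_pen(preset("sparse_day", n_frames=80, seed=7))
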