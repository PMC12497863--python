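import numpy as np
import pytest

from tnkit.config import SimConfig
from tnkit.simulate import GroundTruth, simulate_tracks
from tnkit.tracking import Track, TrackPoint


def make_track(track_id="T000", cell_type="T", xs=(), ys=(), dt=1.0,
               start_frame=0):
    """Build a track from coordinate sequences with uniform frame spacing."""
    return Track(
        track_id=track_id,
        cell_type=cell_type,
        points=tuple(
            TrackPoint(frame=start_frame + i, t=(start_frame + i) * dt,
                       x=float(x), y=float(y))
            for i, (x, y) in enumerate(zip(xs, ys))),
    )


@pytest.fixture
def study_config():
    """The simulated cohort of the deceleration analysis: 20 T cells, 15 of
    them slowing 10-fold on contact and 5 slowing 2-fold, 10% speed noise,
    100 frames."""
    return SimConfig(seed=11, deceleration_factors=[0.1] * 15 + [0.5] * 5,
                     noise_sd_frac=0.1)


@pytest.fixture
def study_truth(study_config) -> GroundTruth:
    return simulate_tracks(study_config)


@pytest.fixture
def small_config():
    """Tiny arena for rendering tests; no transfer painting so each
    channel holds cell bodies only."""
    return SimConfig(seed=5, n_t=2, n_nk=2, n_frames=10, arena_size=200.0,
                     noise_sd_frac=0.0, transfer_pixels=0)
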