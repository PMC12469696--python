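import numpy as np
import pytest

from chromotion import Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_track(xy, dt=1.0, frames=None, observed=None, track_id=None):
    xy = np.asarray(xy, dtype=np.float64)
    n = xy.shape[0]
    if frames is None:
        frames = np.arange(n)
    if observed is None:
        observed = np.ones(n, bool)
    return Trajectory(frames, xy, observed, dt, track_id=track_id)


@pytest.fixture
def random_track(rng):
    def _make(n=12, dt=0.412, scale=0.1):
        return make_track(rng.normal(0, scale, size=(n, 2)), dt=dt)
    return _make
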