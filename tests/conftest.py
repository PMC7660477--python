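import numpy as np
import pytest

from maptrace.trafficking import Track


@pytest.fixture
def make_track():
    """Factory for tracks from a raw position list."""

    def _make(positions, track_id="t0", group="control", dt=0.5, px=0.1):
        return Track(
            track_id=track_id,
            group=group,
            frame_interval_s=dt,
            positions=np.asarray(positions, dtype=float),
            pixel_size_um=px,
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(42)
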