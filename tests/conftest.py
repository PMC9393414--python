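import numpy as np
import pytest

from somnocam.movement import MovementSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_series(rng, n=1200, high=500, roi_area=10_000) -> MovementSeries:
    """A movement series with independent uniform counts (no structure)."""
    return MovementSeries(
        rng.integers(0, high, n),
        rng.integers(0, high, n),
        sample_interval=0.5,
        roi_area=roi_area,
    )


@pytest.fixture
def series(rng) -> MovementSeries:
    return random_series(rng)
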