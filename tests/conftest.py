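import numpy as np
import pytest

from nanosieve.signal_io import Squiggle


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def calibration():
    return dict(offset=10.0, range_pA=1500.0, digitisation=8192.0,
                sampling_rate=4000.0)


@pytest.fixture
def three_squiggles(rng, calibration):
    """Three short raw reads with deliberately unsorted ids."""
    return [
        Squiggle(read_id=rid, raw=rng.integers(300, 700, size=n).astype(np.int16),
                 label=label, **calibration)
        for rid, n, label in [("zeta", 120, 1), ("alpha", 80, 0), ("mid", 100, None)]
    ]
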