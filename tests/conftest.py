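import numpy as np
import pytest

from coldface import RRSeries, build_mist_protocol


@pytest.fixture(scope="session")
def protocol():
    return build_mist_protocol()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def rr_from_intervals(rr_ms, t0=0.0):
    """Build an RRSeries from a list of interval lengths (ms)."""
    rr_ms = np.asarray(rr_ms, dtype=float)
    beats = t0 + np.concatenate([[0.0], np.cumsum(rr_ms) / 1000.0])
    return RRSeries(beat_times_s=beats, rr_ms=rr_ms)
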