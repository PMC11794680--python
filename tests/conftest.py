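import numpy as np
import pytest

from ppgval import IbiSeries


def series_from_ibis(ibis, start_ms=0, device_id="dev", participant_id="p"):
    """Build an IbiSeries from interval values, onsets cumulative from start."""
    ibis = np.asarray(ibis, dtype=float)
    onsets = start_ms + np.round(np.cumsum(ibis)).astype(np.int64)
    return IbiSeries(device_id, participant_id, onsets, ibis)


@pytest.fixture
def make_series():
    return series_from_ibis


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
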