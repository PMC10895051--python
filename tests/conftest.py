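import numpy as np
import pytest

from spanlsci import FluxTrace


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_trace(values, rate=25.0):
    return FluxTrace(np.asarray(values, dtype=float), sampling_rate=rate)


@pytest.fixture
def two_peak_trace():
    """Two clean diastolic peaks of heights 10 and 12 with an intervening low."""
    return make_trace([0, 5, 10, 5, 0, 6, 12, 6, 0])
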