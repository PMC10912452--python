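import numpy as np
import pytest

from finemotor.signal_io import AccelTrace, ScalarSeries
from finemotor.synthetic import BlockSimParams, simulate_block


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_block():
    """Noiseless 40-event tapping block with ground truth."""
    params = BlockSimParams(
        noise_sd=0.0, drift_amplitude=0.0, tremor_amplitude=0.0, rng_seed=7
    )
    return simulate_block(params)


@pytest.fixture
def noisy_block():
    params = BlockSimParams(noise_sd=1.0, rng_seed=11)
    return simulate_block(params)


@pytest.fixture
def small_trace(rng):
    n, fs = 2000, 1000.0
    return AccelTrace(
        time=np.arange(n) / fs,
        ax=rng.normal(size=n),
        ay=rng.normal(size=n),
        az=rng.normal(size=n),
        sampling_rate_hz=fs,
        meta={"subject_id": "S01", "movement_type": "finger_tapping"},
    )


def series(values, fs=1000.0):
    return ScalarSeries(values=np.asarray(values, dtype=float), sampling_rate_hz=fs)


@pytest.fixture
def make_series():
    return series
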