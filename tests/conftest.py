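import numpy as np
import pytest

from netstates.containers import ParcelTimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_noise_ts(rng):
    """Two-parcel unit-variance white noise, 250 Hz, 200 s."""
    return ParcelTimeSeries(rng.standard_normal((2, 50_000)), 250.0)


@pytest.fixture(scope="session")
def hmm_recovery_result():
    """Shared parameter-recovery run at the reference problem size
    (5 channels, 3 states, 10 subjects x 20000 samples)."""
    from netstates.experiments import hmm_recovery

    return hmm_recovery(seed=0)
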