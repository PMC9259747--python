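import numpy as np
import pytest

from eegevt.features import CWTConfig
from eegevt.synth import SynthConfig, generate_recording

#: band-limited grid: cheap but identical feature values inside the band
BAND_CWT = CWTConfig(freq_range=(2.0, 5.0), n_freqs=7, single_precision=True)


@pytest.fixture(scope="session")
def short_recording():
    """10-minute, 6-channel recording with one strong seizure."""
    cfg = SynthConfig(duration=600, n_channels=6, n_seizures=1, seed=7,
                      artifact_rate=0.0, slow_artifact_rate=0.0)
    return generate_recording(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
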