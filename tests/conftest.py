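import numpy as np
import pytest

from tapburst import SynthConfig, gen_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """One fast ground-truth-only synthetic session shared across tests."""
    cfg = SynthConfig(n_channels=4, duration_s=120.0, seed=77)
    _, events, gt = gen_session(cfg, with_waveforms=False)
    return cfg, events, gt
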