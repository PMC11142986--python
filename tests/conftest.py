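import numpy as np
import pytest

from coregload import synth


@pytest.fixture(scope="session")
def reading_session():
    """Small simulated reading session with blinks (30 s, 4 conditions)."""
    cfg = synth.SimConfig(
        seed=21, n_paragraphs=2, paragraph_duration_s=15.0, blink_rate_per_min=15.0
    )
    eeg, et, eeg_ev, et_ev, truth = synth.simulate_session(cfg)
    return cfg, eeg, et, eeg_ev, et_ev, truth


@pytest.fixture(scope="session")
def noblink_session():
    """Blink-free session for saccade/fixation recovery checks."""
    cfg = synth.SimConfig(
        seed=5, n_paragraphs=2, paragraph_duration_s=15.0, blink_rate_per_min=0.0
    )
    eeg, et, eeg_ev, et_ev, truth = synth.simulate_session(cfg)
    return cfg, eeg, et, eeg_ev, et_ev, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
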