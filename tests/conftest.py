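import logging

import numpy as np
import pytest

from cardiofuse import evaluate, synth
from cardiofuse.types import BeatAnnotations

logging.disable(logging.WARNING)

FS = 100.0


@pytest.fixture(scope="session")
def models():
    return synth.default_models()


@pytest.fixture(scope="session")
def const_rr_channel(models):
    """120 s of clean PPG at a perfectly constant 1000-ms RR."""
    hrv = synth.HRVModel(mean_rr=1000, sd_rr=0, rsa_depth=0)
    beats = synth.sample_beat_times(120, hrv, 0)
    ch = synth.render_channel(beats, models["PPG"], FS, 120, 1)
    refs = evaluate.reference_intervals(
        BeatAnnotations(np.round(beats * FS).astype(int)), FS
    )
    return ch, beats, refs


@pytest.fixture(scope="session")
def noise_channel():
    """120 s of pure Gaussian noise shaped like a PPG channel."""
    m = synth.ModalityModel("PPG", np.zeros(16), noise_sd=1.0)
    return synth.render_channel([], m, FS, 120, 2)


@pytest.fixture(scope="session")
def protocol_recording():
    """The standard synthetic motion-protocol session (seed 1)."""
    return synth.generate_session(synth.SessionConfig(), 1)


@pytest.fixture(scope="session")
def quiet_recording():
    """A 5-min quiet session with physiologic HRV (seed 3)."""
    return synth.generate_session(synth.quiet_config(300), 3)
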