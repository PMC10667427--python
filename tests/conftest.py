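import numpy as np
import pytest

import emgseq as E


@pytest.fixture(scope="session")
def noise():
    return E.default_noise()


@pytest.fixture(scope="session")
def profiles():
    return E.default_profiles()


@pytest.fixture(scope="session")
def subject_recordings(profiles, noise):
    """One simulated subject: 50 repetitions of each of the four gestures."""
    return E.generate_dataset(profiles, noise, 50, seed=1234, subject_id="S1")


@pytest.fixture(scope="session")
def rest_recordings(noise):
    """Rest-only acquisitions for false-activation experiments."""
    return E.generate_dataset([E.rest_profile()], noise, 100, seed=4321,
                              subject_id="SR")


@pytest.fixture(scope="session")
def fitted(subject_recordings):
    """End-to-end fit at #step = 4 with the NLR classifier."""
    model = E.SequenceClassifier(subject_recordings, n_steps=4,
                                 classifier="nlr")
    return model.fit(seed=0)


def make_recording(channel_signals=None, n=4000, fs=1000.0, base=0.0,
                   label="Tip", truth=None):
    """Recording with constant ``base`` and explicit per-channel signals.

    ``channel_signals`` maps channel number (1..6) to a full-length array.
    """
    samples = np.full((n, 6), base)
    for ch, sig in (channel_signals or {}).items():
        samples[:, ch - 1] = sig
    return E.EnvelopeRecording(samples=samples, label=label, fs=fs,
                               truth=truth)


@pytest.fixture
def step_recording():
    """All channels at 0 V; channel 2 steps to 1 V at 600 ms and stays."""
    sig = np.zeros(4000)
    sig[600:] = 1.0
    return make_recording({2: sig})
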