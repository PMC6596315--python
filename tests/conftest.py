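import numpy as np
import pytest

from tonelab.synth import (
    DEFAULT_RATE,
    TONE1,
    TONE4,
    UtteranceSpec,
    make_speaker_profile,
    synthesize_utterance,
)

NO_JITTER = dict(duration_frac=0.0, intensity_db=0.0, f0_st=0.0)


@pytest.fixture(scope="session")
def rate():
    return DEFAULT_RATE


@pytest.fixture(scope="session")
def nh_profile():
    prof = make_speaker_profile("NH", 220.0, seed=11)
    prof.jitter_sd = dict(NO_JITTER)
    return prof


@pytest.fixture(scope="session")
def ci_profile():
    prof = make_speaker_profile("CI", 220.0, seed=12)
    prof.jitter_sd = dict(NO_JITTER)
    return prof


@pytest.fixture(scope="session")
def nh_tone4_utterance(nh_profile):
    return synthesize_utterance(UtteranceSpec(nh_profile, TONE4, 1))


@pytest.fixture(scope="session")
def nh_tone1_utterance(nh_profile):
    return synthesize_utterance(UtteranceSpec(nh_profile, TONE1, 1))


def sine(freq_hz, dur_s, rate=DEFAULT_RATE, amp=0.5):
    t = np.arange(int(rate * dur_s)) / rate
    return amp * np.sin(2 * np.pi * freq_hz * t)
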