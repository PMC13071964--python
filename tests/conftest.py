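import numpy as np
import pytest

from caprilung import audio_io, features, preprocess, synthetic


@pytest.fixture(scope="session")
def rate():
    return 8000


@pytest.fixture(scope="session")
def bank(rate):
    return features.make_filterbank(64, 50.0, 2000.0, rate)


@pytest.fixture(scope="session")
def firs(bank, rate):
    return features.filterbank_firs(bank, rate)


@pytest.fixture(scope="session")
def bandpass_spec(rate):
    return preprocess.BandpassSpec(rate=rate)


@pytest.fixture(scope="session")
def normal_recording():
    params = synthetic.SynthesisParams(label=0, breaths_per_min=20.0, seed=42)
    return synthetic.synth_recording(params)


def tone_segment(freq_hz, rate=8000, duration_s=2.0, label=None):
    t = np.arange(int(duration_s * rate)) / rate
    return audio_io.LabeledSegment(
        samples=np.sin(2 * np.pi * freq_hz * t),
        rate=rate,
        start_time=0.0,
        label=label,
        source_id=f"tone{freq_hz:.0f}",
    )


@pytest.fixture(scope="session")
def small_image_batch():
    """Tiny fixed batch of standardized 3-channel images plus labels."""
    rng = np.random.default_rng(7)
    x = rng.standard_normal((8, 3, 96, 96))
    y = np.array([0, 1, 2, 3, 0, 1, 2, 3])
    return x, y
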