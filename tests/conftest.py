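import numpy as np
import pytest

from cardioish import BeatTemplate, generate_beatset
from cardioish.synthetic import example_profiles


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def short_template():
    """Default-shaped template shrunk to 60 samples for fast tests."""
    return BeatTemplate(
        wave_centers=(18.0, 28.0, 30.0, 32.0, 44.0),
        wave_widths=(2.0, 1.0, 1.2, 1.0, 3.0),
        wave_amplitudes=(0.15, -0.10, 1.00, -0.25, 0.35),
        length=60,
    )


@pytest.fixture
def positive_template():
    """Strictly positive waveform (all wave amplitudes positive): under a
    strict gain ordering with zero offsets and no noise, the lead ranking is
    the same permutation at every sample — the analytic transform oracle."""
    return BeatTemplate(
        wave_centers=(8.0, 20.0, 30.0, 40.0, 52.0),
        wave_widths=(3.0, 2.0, 2.5, 2.0, 5.0),
        wave_amplitudes=(0.2, 0.3, 1.0, 0.4, 0.25),
        length=60,
    )


@pytest.fixture
def two_class_profiles():
    return example_profiles(2)


@pytest.fixture
def clean_beats(short_template, two_class_profiles):
    return generate_beatset(two_class_profiles, 12, short_template, rng_seed=42)


def random_beat(rng, n_samples=20):
    """Continuous random beat: ties have probability zero."""
    return rng.normal(0.0, 1.0, size=(12, n_samples))
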