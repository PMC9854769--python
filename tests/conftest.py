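import numpy as np
import pytest

from eegmusic import FeatureConfig, SubspaceConfig, SyntheticSpec, simulate_trial


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """8-channel, 10 s trial spec: quick but spectrally realistic."""
    return SyntheticSpec(n_channels=8, duration=10.0, seed=7)


@pytest.fixture
def tone_spec():
    """Deterministic single-tone spec: 10 Hz alpha at 20 uV, nothing else."""
    return SyntheticSpec(
        n_channels=3, duration=10.0, seed=7,
        band_powers={"neutral": {"alpha": 20.0}},
        band_centers={"alpha": 10.0},
        noise_scale=0.0, powerline_amplitude=0.0,
        blink_rate=0.0, blink_amplitude=0.0,
    )


@pytest.fixture
def small_feature_cfg():
    """Windowing sized for 10 s test trials."""
    return FeatureConfig(window_length=512,
                         subspace=SubspaceConfig(L=20, p=3))


@pytest.fixture
def tone_trial(tone_spec):
    return simulate_trial(tone_spec, "neutral")
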