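import numpy as np
import pytest

from gaitdpf import SynthConfig, simulate_recording


@pytest.fixture(scope="session")
def clean_config() -> SynthConfig:
    """Noise-free cohort: labeling must recover truth exactly on this."""
    return SynthConfig(
        n_subjects=2,
        noise_sd=0.0,
        packet_loss_rate=0.0,
        swl_thigh_artifact=False,
        sulhs_foot_artifact=False,
        seed=42,
    )


@pytest.fixture(scope="session")
def clean_recording(clean_config):
    return simulate_recording(clean_config, "S01", 1.5)


@pytest.fixture(scope="session")
def noisy_config() -> SynthConfig:
    """Default-condition cohort (sensor noise, packet loss, bursts)."""
    return SynthConfig(n_subjects=2, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
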