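import numpy as np
import pytest

from eegsr.synth import SynthConfig, generate_erders_trialset, lateralized_erd_depth
from eegsr.trialset import EEGTrialSet


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_synth() -> EEGTrialSet:
    """A small, strongly separable two-class set (fast shared fixture)."""
    cfg = SynthConfig(
        trials_per_class=20,
        n_channels=8,
        trial_duration=1.5,
        task_window=(0.25, 1.25),
        erd_depth=lateralized_erd_depth(2, 8, 0.8),
        pink_noise_sd=1.0,
    )
    return generate_erders_trialset(cfg, seed=99)


@pytest.fixture()
def sinusoid_trialset():
    """Deterministic 10 Hz + 20 Hz multichannel set for signal-path tests."""
    fs = 250.0
    t = np.arange(500) / fs
    rng = np.random.default_rng(7)
    phases = rng.uniform(0, 2 * np.pi, size=(6, 4))
    data = 10 * np.sin(2 * np.pi * 10 * t + phases[:, :, None]) + 4 * np.sin(
        2 * np.pi * 20 * t + phases[:, ::-1, None]
    )
    return EEGTrialSet(data, fs=fs, labels=np.arange(6) % 2, scope=(-40.0, 40.0))
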