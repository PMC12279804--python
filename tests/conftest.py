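import numpy as np
import pytest

from erpdecode import EpochSet, NoiseSpec, SynthConfig
from erpdecode.simulate import CHANNELS_30


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """A small but structurally default cohort configuration."""
    return SynthConfig(n_subjects_per_group=2, trials_per_run=32, seed=99)


@pytest.fixture
def silent_config():
    """Noise-free configuration: epochs are deterministic component sums."""
    return SynthConfig(
        n_subjects_per_group=1, trials_per_run=4, noise=NoiseSpec.silent(), seed=5
    )


def make_epochs(
    data: np.ndarray,
    srate: float = 256.0,
    t0: float = -200.0,
    run_labels=None,
    subject_id: str = "s1",
    group: str = "placebo",
) -> EpochSet:
    """Wrap a raw (trials, channels, samples) array into an EpochSet."""
    n_trials, n_channels, n_samples = data.shape
    times = t0 + np.arange(n_samples) * 1000.0 / srate
    if run_labels is None:
        run_labels = np.ones(n_trials, dtype=int)
    names = (CHANNELS_30 * (n_channels // 30 + 1))[:n_channels]
    return EpochSet(
        data=data,
        times=times,
        srate=srate,
        channel_names=names,
        run_labels=run_labels,
        subject_id=subject_id,
        group=group,
    )
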