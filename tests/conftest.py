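import numpy as np
import pytest

from spikespeech import ConvConfig, SynthSpec, sample_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cfg():
    """Tiny conv geometry for brute-force oracle comparisons."""
    return ConvConfig(
        n_maps=2,
        win_len=3,
        stride=1,
        n_sections=3,
        v_thresh=2.0,
        n_frames=8,
        n_bands=3,
        init_mean=0.5,
        init_sd=0.2,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The default 4-class synthetic dataset (shared across tests)."""
    return sample_dataset(SynthSpec(seed=7))


def random_raster(rng, n_frames, n_bands, n_steps=10, p_silent=0.3):
    """A random latency raster with a mix of spikes and silent neurons."""
    r = rng.integers(0, n_steps, size=(n_frames, n_bands))
    r[rng.random((n_frames, n_bands)) < p_silent] = -1
    return r
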