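import numpy as np
import pytest

from pathsurv import SyntheticSpec, TrainConfig, generate


@pytest.fixture(scope="session")
def small_scenario():
    """A quick, signal-rich cohort for training-path tests."""
    spec = SyntheticSpec(
        n_samples=120,
        n_genes=30,
        pathways=((5, 1), (5, 1)),
        effect_size=2.0,
        noise_sd=0.3,
        seed=42,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def default_scenario():
    """The package's default synthetic scenario (used by the acceptance suite)."""
    return generate(SyntheticSpec())


@pytest.fixture
def fast_config():
    """Few-epoch config for tests that exercise plumbing, not convergence."""
    return TrainConfig(epochs_pretrain=5, epochs_train=5, seed=0, track_cindex=False)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
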