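import numpy as np
import pytest

from neoseg import ArchitectureConfig, PhantomSpec, TrainConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_arch():
    """Smallest architecture that still exercises all four levels."""
    return ArchitectureConfig(filters_per_level=(4, 4, 2, 2), bridge_filters=2, in_channels=2)


@pytest.fixture(scope="session")
def scaled_arch():
    """The scaled-down profile used for desk-scale training checks."""
    return ArchitectureConfig(filters_per_level=(16, 8, 4, 2), bridge_filters=2, in_channels=2)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Three small records for fast cross-validation plumbing tests."""
    spec = PhantomSpec(extents=(16, 16, 16), seed=41)
    return generate_cohort(3, spec)


@pytest.fixture
def stub_train_config():
    return TrainConfig(epochs=1, seed=0)
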