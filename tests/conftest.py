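import numpy as np
import pytest

from bootseg import LabelVolume, SynthConfig, generate_synthetic_labels

VOXEL_SIZE = (40.0, 8.0, 8.0)


@pytest.fixture(scope="session")
def small_synth_labels() -> LabelVolume:
    """A small deterministic synthetic label volume shared across tests."""
    return generate_synthetic_labels(
        SynthConfig(shape=(16, 32, 32), instance_range=(3, 6),
                    min_instance_size=32, seed=42)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_labels(shape, n_labels, seed) -> np.ndarray:
    """Random label array (not spatially coherent; for oracle tests)."""
    return np.random.default_rng(seed).integers(0, n_labels + 1, size=shape)
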