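import numpy as np
import pytest

import agmfs


@pytest.fixture(scope="session")
def worked_example():
    return agmfs.generate_worked_example()


@pytest.fixture(scope="session")
def small_synthetic():
    """A modest two-modality dataset that fits in fractions of a second."""
    spec = agmfs.SyntheticSpec(
        n_samples=60,
        modality_dims=[12, 6],
        n_informative_per_modality=[3, 2],
        effect_size=2.0,
        modality_strength=[0.6, 0.4],
        seed=11,
    )
    return agmfs.generate_dataset(spec)


@pytest.fixture(scope="session")
def default_synthetic():
    """The full-size study shape: n=200, dims [93, 93, 3]."""
    spec = agmfs.SyntheticSpec(seed=7)
    return agmfs.generate_dataset(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
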