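import numpy as np
import pytest

from oscbind import synthetic
from oscbind.containers import TaskDesign


@pytest.fixture(scope="session")
def small_leadfield():
    """Cheap random full-rank forward model for unit tests."""
    return synthetic.make_leadfield(
        12, (6, 6, 6), 1.0, model="random_full_rank", seed=7
    )


@pytest.fixture(scope="session")
def sphere_leadfield():
    return synthetic.make_leadfield(20, (6, 6, 6), 1.0, model="spherical", seed=1)


@pytest.fixture(scope="session")
def scaled_design():
    return TaskDesign.scaled(20)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
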