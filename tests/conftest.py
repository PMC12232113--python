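import numpy as np
import pytest

from neurotwin import make_template, fixture_dataset
from neurotwin.models import ModelSpec, ContrastiveVAE


@pytest.fixture(scope="session")
def template32():
    return make_template((32, 32, 32), seed=0)


@pytest.fixture(scope="session")
def tiny_dataset():
    """16 subjects at 32**3 with exaggerated effects (8 controls, 8 patients)."""
    return fixture_dataset(seed=0)


@pytest.fixture(scope="session")
def tiny_spec():
    return ModelSpec(kind="cvae", input_shape=(16, 16, 16), conv_filters=(4, 6),
                     latent_dim_per_space=2, batch_size=4)


@pytest.fixture()
def tiny_cvae(tiny_spec):
    return ContrastiveVAE(tiny_spec, seed=0)


@pytest.fixture()
def tiny_comorbid():
    spec = ModelSpec(kind="comorbid_cvae", input_shape=(16, 16, 16),
                     conv_filters=(4, 6), latent_dim_per_space=2, batch_size=4)
    return ContrastiveVAE(spec, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
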