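import numpy as np
import pytest
from hypothesis import settings

from parawasp.trees import default_species_tree

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def species_tree():
    return default_species_tree()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
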