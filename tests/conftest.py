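import numpy as np
import pytest

from enzrank.embedders import SurrogateEmbedder, embed_dataset
from enzrank.synthfit import generate_landscape


@pytest.fixture(scope="session")
def landscape():
    """A mid-sized synthetic landscape shared by read-only tests."""
    return generate_landscape(seed=11, n=120)


@pytest.fixture(scope="session")
def embedded_landscape(landscape):
    emb = SurrogateEmbedder(seed=11)
    X = embed_dataset(landscape.dataset.records, emb, layer=1)
    return landscape, emb, X


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
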