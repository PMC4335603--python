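import numpy as np
import pytest

from transpoly.params import model_params


@pytest.fixture
def human_chimp():
    """Parameters plausible for humans and chimpanzees (ancestral size
    50,000; split 250,000 generations; genome-average rates)."""
    return model_params(Ne=10_000, Na=50_000, T=250_000, p=0.5, r=1.2e-8, mu=1.2e-8)


@pytest.fixture
def drosophila():
    """Large-Ne, old-split regime (D. melanogaster / D. simulans)."""
    return model_params(Ne=1_000_000, Na=1_000_000, T=2e7, p=0.5, r=1.2e-8, mu=1.2e-8)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
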