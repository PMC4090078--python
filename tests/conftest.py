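import numpy as np
import pytest

from credence import DiscreteOpinion


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_opinion(rng, k, total_mass=1.0, floor=0.0):
    """Dirichlet-random opinion; ``floor > 0`` keeps every event positive."""
    w = rng.dirichlet(np.ones(k)) + floor
    return DiscreteOpinion.from_weights(w, total_mass)
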