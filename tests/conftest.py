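import itertools

import numpy as np
import pytest

from methrank.ising import MethylationPMF


def enum_level_pmf(field, coupling) -> np.ndarray:
    """Brute-force level PMF by enumerating all 2^L methylation patterns."""
    field = np.asarray(field, float)
    coupling = np.asarray(coupling, float)
    L = field.size
    probs = np.zeros(L + 1)
    for bits in itertools.product((0, 1), repeat=L):
        x = np.array(bits)
        energy = float(field @ x)
        if L > 1:
            energy += float(coupling @ (x[:-1] * x[1:]))
        probs[x.sum()] += np.exp(energy)
    return probs / probs.sum()


def random_pmf(rng: np.random.Generator, L: int) -> MethylationPMF:
    p = rng.dirichlet(np.ones(L + 1) * 0.8)
    return MethylationPMF(L, p)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
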