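import itertools

import numpy as np
import pytest

from rfa.genotype_space import GenotypeSpace, enumerate_genotypes
from rfa.rfa_exact import PhenotypeTable

# exhaustive battery of small spaces (q <= 3, n <= 4, plus one mixed)
SMALL_SPACES = [
    (2, 2),
    (2, 3),
    (2, 4),
    (3, 2),
    (3, 3),
    (3, 4),
]


def make_space(q, n):
    return GenotypeSpace.uniform(q, n)


@pytest.fixture(params=SMALL_SPACES, ids=lambda p: f"{p[0]}^{p[1]}")
def small_space(request):
    q, n = request.param
    return GenotypeSpace.uniform(q, n)


@pytest.fixture
def mixed_space():
    return GenotypeSpace.from_sizes([3, 2, 2])


def random_table(space, seed=0, n_replicates=1, sd=1.0):
    """Complete random landscape on a space."""
    g = enumerate_genotypes(space)
    rng = np.random.default_rng(seed)
    y = rng.normal(0.0, sd, size=(space.n_genotypes, n_replicates))
    return PhenotypeTable(space, g, y)


def brute_force_effects(space, y_flat, max_order):
    """Independent oracle: reference-free effects by literal nested subset
    averaging of the definitions, scanning the enumerated genotype list.

    Shares no code with the production decomposition (no tensor reshapes,
    no axis arithmetic): subset means are computed by filtering genotype
    tuples, and each term subtracts the explicitly accumulated
    lower-order expectation.
    """
    genos = list(itertools.product(*[range(q) for q in space.shape]))
    assert len(genos) == len(y_flat)
    effects = {((), ()): float(np.mean(y_flat))}
    for k in range(1, max_order + 1):
        for sites in itertools.combinations(range(space.n_sites), k):
            for states in itertools.product(*[range(space.shape[i]) for i in sites]):
                match = [
                    y
                    for g, y in zip(genos, y_flat)
                    if all(g[i] == s for i, s in zip(sites, states))
                ]
                expected = 0.0
                for r in range(k):
                    for sub in itertools.combinations(range(k), r):
                        key_sites = tuple(sites[j] for j in sub)
                        key_states = tuple(states[j] for j in sub)
                        expected += effects[(key_sites, key_states)]
                effects[(sites, states)] = float(np.mean(match)) - expected
    return effects
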