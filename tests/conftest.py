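import numpy as np
import pytest

from pathpid import named_distribution, random_channel_system, random_markov_chain

FIXTURE_NAMES_3VAR = [
    "common_cause_3var",
    "neg_synergy_3var",
    "dyadic",
    "triadic",
    "pwunq",
    "5a",
    "5b",
    "5c",
    "reduced_or",
    "xor",
    "and",
    "or",
    "sum",
    "two_bit_copy",
]


@pytest.fixture(scope="session")
def named(request=None):
    cache = {}

    def get(name):
        if name not in cache:
            cache[name] = named_distribution(name)
        return cache[name]

    return get


@pytest.fixture(scope="session")
def table3a(named):
    return named("common_cause_3var")


@pytest.fixture(scope="session")
def two_bit_copy(named):
    return named("two_bit_copy")


@pytest.fixture(scope="session")
def random_systems_small():
    """A modest pool of generic 3-variable systems for unit-level sweeps."""
    return [random_channel_system(3, 2, edge_density=1.0, seed=s) for s in range(60)]


@pytest.fixture(scope="session")
def random_chains_small():
    return [random_markov_chain((2, 2, 2), seed=s) for s in range(60)]
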