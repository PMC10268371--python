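import numpy as np
import pytest

from pktaxa import GeneratorConfig, SecondaryStructure


def random_structure(rng: np.random.Generator, length: int = 40,
                     n_pairs: int = 8) -> SecondaryStructure:
    """Uniformly random partial matching with arc span >= 2.

    Unlike the package generators this makes no attempt at realism:
    arcs may cross arbitrarily, which is exactly what the brute-force
    oracles need.
    """
    free = list(range(1, length + 1))
    pairs = set()
    attempts = 0
    while len(pairs) < n_pairs and attempts < 200:
        attempts += 1
        i, j = rng.choice(len(free), size=2, replace=False)
        a, b = free[min(i, j)], free[max(i, j)]
        if b - a >= 2:
            pairs.add((a, b))
            free = [p for p in free if p not in (a, b)]
    return SecondaryStructure(length=length, pairs=frozenset(pairs))


@pytest.fixture
def rng():
    return np.random.default_rng(20230615)


@pytest.fixture
def base_config():
    return GeneratorConfig(seed=7)
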