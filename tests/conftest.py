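import random

import numpy as np
import pandas as pd
import pytest

from morphocline.datasets import load_specimen_matrix
from morphocline.parsimony import Character, CharacterMatrix


@pytest.fixture(scope="session")
def specimen_table():
    return load_specimen_matrix()


@pytest.fixture(scope="session")
def ingroup(specimen_table):
    return specimen_table[~specimen_table["outgroup"]].reset_index(drop=True)


def random_discrete_matrix(rng: random.Random, ntax: int, nchar: int,
                           max_states: int = 4, additive_p: float = 0.5,
                           missing_p: float = 0.0) -> CharacterMatrix:
    """Small random matrix for oracle comparisons."""
    chars = []
    for _ in range(nchar):
        k = rng.randrange(2, max_states + 1)
        states = []
        for _ in range(ntax):
            if missing_p and rng.random() < missing_p:
                states.append(None)
            else:
                states.append(frozenset([rng.randrange(k)]))
        if all(s is None for s in states):
            states[0] = frozenset([0])
        chars.append(Character(states=states, additive=rng.random() < additive_p))
    return CharacterMatrix(taxa=[f"t{i}" for i in range(ntax)], characters=chars)
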