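import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from partstree.matrix import AbundanceMatrix, CodedMatrix


@pytest.fixture
def quartet_matrix() -> CodedMatrix:
    """The worked quartet: one ordered character, A=0 B=2 C=4 D=6."""
    return CodedMatrix(part_ids=list("ABCD"), proteome_ids=["c1"],
                       states=np.array([[0], [2], [4], [6]]),
                       alphabet_size=7)


@pytest.fixture
def small_abundance() -> AbundanceMatrix:
    counts = np.array([[0, 5, 9],
                       [1, 5, 0],
                       [10, 5, 1],
                       [100, 5, 4],
                       [1000, 5, 0]])
    return AbundanceMatrix(part_ids=list("abcde"),
                           proteome_ids=["g1", "g2", "g3"], counts=counts)


def random_coded(rng: np.random.Generator, n_taxa: int, n_chars: int,
                 n_states: int) -> CodedMatrix:
    states = rng.integers(0, n_states, size=(n_taxa, n_chars))
    return CodedMatrix(part_ids=[f"t{i}" for i in range(n_taxa)],
                       proteome_ids=[f"c{j}" for j in range(n_chars)],
                       states=states, alphabet_size=max(n_states, 2))
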