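import numpy as np
import pytest

from metriomorph import PipelineConfig
from metriomorph.parsimony.matrix import CharacterMatrix


@pytest.fixture
def cfg():
    return PipelineConfig(rng_seed=0)


@pytest.fixture
def toy_matrix():
    """Four taxa, three unordered characters, no missing data."""
    return CharacterMatrix(
        taxa=("A", "B", "C", "D"),
        states=np.array([[0, 0, 1], [0, 1, 1], [1, 0, 0], [1, 1, 0]]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
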