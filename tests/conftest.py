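import numpy as np
import pytest

import foldgraph as fg
from foldgraph.synthetic import random_rotation


@pytest.fixture(scope="session")
def tiny_benchmark():
    """4 archetypes x 5 members, lengths 30-45: cheap shared dataset."""
    spec = fg.SyntheticDatasetSpec(
        n_archetypes=4,
        members_per_archetype=5,
        length_range=(30, 45),
        seed=7,
    )
    structures, table, labels = fg.make_benchmark(spec)
    return structures, table, labels


@pytest.fixture(scope="session")
def tiny_graphs(tiny_benchmark):
    structures, _, _ = tiny_benchmark
    return [fg.featurize(s) for s in structures]


@pytest.fixture(scope="session")
def small_encoder():
    return fg.GraphEncoder(fg.EncoderConfig.small(), seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def rigid_transform(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply a random rotation + translation (helper for invariance tests)."""
    R = random_rotation(rng)
    t = rng.uniform(-40.0, 40.0, size=3)
    return coords @ R.T + t
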