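import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from hetmda import AssociationMatrix, FixtureSpec, SimilarityMatrix, make_fixture

from oracles import random_symmetric_similarity


@pytest.fixture(scope="session")
def small_fixture():
    """A 12 x 15 planted-block study used across the suite."""
    return make_fixture(FixtureSpec(n_d=12, n_m=15, n_blocks=3, seed=7))


@pytest.fixture(scope="session")
def default_fixture():
    """The default-size 60 x 80 planted-block study."""
    return make_fixture(FixtureSpec(seed=11))


def random_association(rng, n_d, n_m, density=0.35):
    """Binary matrix with at least one positive in some row and column."""
    values = (rng.random((n_d, n_m)) < density).astype(float)
    if values.sum() == 0:
        values[rng.integers(n_d), rng.integers(n_m)] = 1.0
    return AssociationMatrix(
        values,
        [f"d{i:02d}" for i in range(n_d)],
        [f"m{j:02d}" for j in range(n_m)],
    )


def random_similarity(rng, ids, kind="integrated"):
    return SimilarityMatrix(random_symmetric_similarity(rng, len(ids)), list(ids), kind)
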