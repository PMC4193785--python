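import numpy as np
import pytest

from copulaclust import WeightedBipartiteMatrix, supreme_court


@pytest.fixture
def rng():
    return np.random.default_rng(20140)


@pytest.fixture(scope="session")
def court():
    """The packaged 9-justice x 26-issue signed voting matrix."""
    return supreme_court()


@pytest.fixture
def small_matrix(rng):
    """A 4-actor x 30-feature matrix with two planted comoving pairs."""
    base = rng.normal(size=(2, 30))
    values = np.vstack(
        [
            base[0],
            base[0] + 0.1 * rng.normal(size=30),
            base[1],
            base[1] + 0.1 * rng.normal(size=30),
        ]
    )
    return WeightedBipartiteMatrix(("a", "b", "c", "d"), tuple(f"f{i}" for i in range(30)), values)
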