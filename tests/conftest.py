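import numpy as np
import pytest

from ublsurf import synth


@pytest.fixture(scope="session")
def helix10():
    structure, truth = synth.make_structure(10, "helix", seed=11)
    return structure, truth


@pytest.fixture(scope="session")
def strand20():
    structure, truth = synth.make_structure(20, "strand", seed=21)
    return structure, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
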