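import numpy as np
import pytest

from gnnr import GeneratorConfig, LongitudinalDataset, generate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A reduced simulated dataset with ground truth (fast to fit)."""
    return generate_dataset(config=GeneratorConfig(n_per_class=10, n_background=60, seed=11))


@pytest.fixture(scope="session")
def default_sim():
    """One full-size default dataset (1500 x 100 x 4), generated once."""
    return generate_dataset(config=GeneratorConfig(seed=1))


def random_dataset(seed: int, d: int = 12, n: int = 10, T: int = 3) -> LongitudinalDataset:
    """Small unstructured dataset for solver property tests."""
    rng = np.random.default_rng(seed)
    cube = rng.normal(size=(d, n, T))
    labels = np.ones(n, dtype=int)
    labels[n // 2 :] = -1
    return LongitudinalDataset(cube=cube, labels=labels)
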