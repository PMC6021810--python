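import numpy as np
import pytest

from rainbowspec.synthetic_data import (
    PopulationSpec,
    SceneSpec,
    make_feature_population,
    make_rainbow_image,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_scene():
    """One clean default scene with its ground truth."""
    return make_rainbow_image(SceneSpec())


@pytest.fixture(scope="session")
def small_population():
    """A reduced nonlinear population (n=48) for fast classifier tests."""
    spec = PopulationSpec(n_per_cell=8, seed=7, certify=False)
    fm, params = make_feature_population(spec)
    return fm, params


@pytest.fixture(scope="session")
def binary_toy():
    """A 24-sample linearly separable 2-class problem in 5 dimensions."""
    gen = np.random.default_rng(5)
    X = gen.normal(size=(24, 5))
    X[12:, 0] += 6.0
    y = np.array(["neg"] * 12 + ["pos"] * 12, dtype=object)
    return X, y
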