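import numpy as np
import pytest

import ecograd as eg


@pytest.fixture(scope="session")
def small_params():
    return eg.default_params(n_plants=400, seed=7)


@pytest.fixture(scope="session")
def small_pop(small_params):
    return eg.generate_population(small_params)


@pytest.fixture(scope="session")
def tiny_spec():
    # reduced basis dimensions keep the suite fast; the generating
    # surface is quadratic, well inside this spline span
    return eg.SmoothSpec(k_main=5, k_interaction=4, k_spatial=4)


@pytest.fixture(scope="session")
def fitted_small(tiny_spec, small_pop):
    return eg.fit_surface(tiny_spec, small_pop)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
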