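import logging

import numpy as np
import pytest
from hypothesis import settings

from riskstrat import default_config, generate_population, score_population, toy_model

logging.getLogger("riskstrat").setLevel(logging.ERROR)

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy():
    return toy_model()


@pytest.fixture(scope="session")
def default_population():
    """The shipped calibration run: n = 40,000 under the default config."""
    return generate_population(default_config(40_000, seed=20210318))


@pytest.fixture(scope="session")
def default_scores(default_population, toy):
    pop = default_population
    return score_population(pop.patients, pop.diagnoses, toy).to_numpy()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
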