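import numpy as np
import pytest

from cannorm.datasets import census_table_summaries, load_census_table
from cannorm.synthetic_data import GeneratorParams, generate_study


@pytest.fixture(scope="session")
def census_table():
    """The packaged 11-population census/distribution table."""
    return load_census_table()


@pytest.fixture(scope="session")
def census_summaries():
    return census_table_summaries()


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by read-only tests."""
    params = GeneratorParams(n_tanks=6, n_per_tank=20, n_solitary=15)
    return generate_study(params, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
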