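import numpy as np
import pytest

import ga1cea as g


@pytest.fixture(scope="session")
def config():
    return g.load_config()


@pytest.fixture(scope="session")
def life_table(config):
    return g.build_life_table(config.life_expectancy_at_birth, config.max_age)


@pytest.fixture(scope="session")
def base(config):
    return g.base_case(config)


@pytest.fixture(scope="session")
def zero_mortality():
    """Life table with no background deaths (110 ages)."""
    return g.LifeTable(np.zeros(110))
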