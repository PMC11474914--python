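import pytest
from hypothesis import settings

from hba1c_cea import load_and_validate
from hba1c_cea.lifetable import make_life_table
from hba1c_cea.synthetic import default_truth, simulate_panel

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def config():
    return load_and_validate()


@pytest.fixture(scope="session")
def life_table():
    return make_life_table()


@pytest.fixture(scope="session")
def panel_6m_seed1():
    """Moderate 6-monthly synthetic panel reused across estimation tests."""
    return simulate_panel(default_truth(), 6, 2000, 5, seed=1)
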