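import numpy as np
import pytest

from soilwater import synthetic


@pytest.fixture(scope="session")
def driver_table():
    """Bundled 21-month reference driver forecast table."""
    return synthetic.xilingol_driver_forecast()


@pytest.fixture(scope="session")
def sm_table():
    """Bundled depth-resolved moisture forecast matching driver_table."""
    return synthetic.xilingol_sm_forecast()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_site():
    """One default synthetic site record, shared across tests."""
    sc = synthetic.SiteScenario(years=10, seed=3)
    drivers, profile, truth = synthetic.generate(sc)
    return sc, drivers, profile, truth
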