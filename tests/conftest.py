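import warnings

import pytest
from hypothesis import HealthCheck, settings

from peatbudget import SiteScenario, load_twitchell_2012

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.filter_too_much],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def twitchell():
    """Published site-level inputs for both Twitchell Island fields."""
    inputs, meta = load_twitchell_2012()
    return inputs, meta


@pytest.fixture(scope="session")
def site1(twitchell):
    return twitchell[0]["1"]


@pytest.fixture(scope="session")
def site2(twitchell):
    return twitchell[0]["2"]


@pytest.fixture()
def scenario():
    """Default Site-1-like synthetic scenario."""
    return SiteScenario(seed=1)


@pytest.fixture()
def quiet():
    """Suppress pipeline warnings inside noisy estimation loops."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
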