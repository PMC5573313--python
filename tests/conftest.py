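import pytest
from hypothesis import HealthCheck, settings

from gckvar.io import published_kinetic_params
from gckvar.kinetics import BetaCellModelConfig

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def published_params():
    """Published kinetic constants keyed by variant name (WT + 19 variants)."""
    return published_kinetic_params()


@pytest.fixture(scope="session")
def wt(published_params):
    return published_params["WT"]


@pytest.fixture(scope="session")
def beta_cfg():
    return BetaCellModelConfig()
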