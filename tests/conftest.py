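import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ddckit",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ddckit")


@pytest.fixture(scope="session")
def scaffold():
    from ddckit.presets import default_scaffold

    return default_scaffold()


@pytest.fixture(scope="session")
def design_pair(scaffold):
    from ddckit.presets import standard_designs

    return standard_designs(scaffold)


@pytest.fixture(scope="session")
def ddc1(design_pair):
    return design_pair[0]


@pytest.fixture(scope="session")
def ddc2(design_pair):
    return design_pair[1]


@pytest.fixture(scope="session")
def keys(scaffold):
    """(admin, user-1, user-2) for the standard design pair."""
    from ddckit.presets import standard_keys

    return standard_keys(scaffold)


@pytest.fixture(scope="session")
def a5():
    from ddckit.codec import get_scheme

    return get_scheme("a5")
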