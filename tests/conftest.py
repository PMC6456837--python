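import pytest
from hypothesis import HealthCheck, settings

from mangroveval import io as mio

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def pre_table():
    """Published pre-thinning stand table (ages 3-40)."""
    return mio.load_fixture_stand_table("pre")


@pytest.fixture(scope="session")
def post_table():
    """Published post-thinning stand table (ages 18-40)."""
    return mio.load_fixture_stand_table("post")


@pytest.fixture(scope="session")
def pre_refs():
    """Published TV/MAI/PAI columns of the pre-thinning table."""
    return mio.load_fixture_reference_columns("pre").set_index("age")


@pytest.fixture(scope="session")
def post_refs():
    return mio.load_fixture_reference_columns("post").set_index("age")


@pytest.fixture(scope="session")
def valuation_cfg():
    return mio.load_fixture_config("valuation.cfg")
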