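import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # for tests/oracles.py

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def all_profile_fixtures():
    from nasalair.profile_io import iter_profile_fixtures

    return list(iter_profile_fixtures())


@pytest.fixture(scope="session")
def mesh_table():
    from nasalair.profile_io import load_fixture

    return load_fixture("T10")
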