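import pytest
from hypothesis import settings

from agencysim import (
    RunConfig,
    TargetPath,
    assemble_session,
    build_visibility,
    default_profiles,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def path():
    return TargetPath()


@pytest.fixture(scope="session")
def visibility(path):
    return build_visibility(path)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def pb_session(profiles, path):
    """One default session, shared read-only across tests."""
    return assemble_session(profiles["pb_like"], path, seed=42)
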