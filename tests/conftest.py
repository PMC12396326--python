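import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from paleocarb.pipeline import RunConfig, run_reconstruction
from paleocarb.world import build_world


@pytest.fixture(scope="session")
def world():
    """Default synthetic world (full study conditions, seed fixed)."""
    return build_world(seed=7)


@pytest.fixture(scope="session")
def quick_config():
    return RunConfig(seed=3).quick()


@pytest.fixture(scope="session")
def quick_report(quick_config):
    """One CI-scale end-to-end run shared across tests."""
    return run_reconstruction(quick_config)
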