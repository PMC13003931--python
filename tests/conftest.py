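import pytest
from hypothesis import settings

from psiquant.config import default_demo_target

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def target():
    """Synthetic demonstration locus shared across tests."""
    return default_demo_target()
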