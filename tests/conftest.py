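import pytest
from hypothesis import settings

from smartseat import ReadoutConfig

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=100, database=None
)
settings.load_profile("suite")


@pytest.fixture
def cfg() -> ReadoutConfig:
    """Reference-device configuration, default (mean) propagation."""
    return ReadoutConfig()


@pytest.fixture
def sum_cfg() -> ReadoutConfig:
    """Device-literal root-sum-square propagation (paper-fidelity mode)."""
    return ReadoutConfig(uncertainty_propagation="sum")
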