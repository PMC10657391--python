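import pytest
from hypothesis import HealthCheck, settings

import tadote as td

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def panel():
    """Two-locus qHMS1 + qHMS7 panel with complete killing."""
    return td.default_panel()


@pytest.fixture(scope="session")
def sub1():
    """Single-locus qHMS1 panel, k = 1."""
    return td.single_locus_panel("qHMS1")


@pytest.fixture(scope="session")
def reference():
    """Deterministic toy sequence reference for allele typing."""
    return td.gen_reference_toys()
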