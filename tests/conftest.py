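import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import naturalmoves as nm  # noqa: E402


@pytest.fixture(scope="session")
def toy_groove():
    return nm.make_toy_groove()


@pytest.fixture(scope="session")
def mhc_decomposition(toy_groove):
    """Canonical five-segment / three-molten-zone decomposition."""
    return toy_groove.decomposition


@pytest.fixture(scope="session")
def bdna():
    """Unmodified Dickerson-Drew dodecamer duplex."""
    return nm.make_bdna("CGCGAATTCGCG")


@pytest.fixture(scope="session")
def bdna_marked():
    """DDD with symmetric 5hmC marks at position 9 of both strands, hydroxyls
    oriented toward the 3'-adjacent guanine O6."""
    return nm.make_bdna("CGCGAATTCGCG", mods=(("A", 9, "toward"), ("B", 9, "toward")))


@pytest.fixture(scope="session")
def ddd_decomposition(bdna_marked):
    return nm.make_bdna_decomposition(bdna_marked, marks=(("A", 9), ("B", 9)))
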