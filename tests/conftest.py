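import pytest

from expandep import get_model


@pytest.fixture(scope="session")
def model0():
    """Five parallel needles (zero divergence)."""
    return get_model("5n-0deg")


@pytest.fixture(scope="session")
def model10():
    """Four peripheral needles, 10 degree divergence, no central needle."""
    return get_model("4n-10deg")


@pytest.fixture(scope="session")
def model20():
    """Five needles, 20 degree divergence."""
    return get_model("5n-20deg")
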