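import pytest

from rtsig import make_fixture


@pytest.fixture(scope="session")
def bundle():
    """Deterministic fixture bundle shared by the slower end-to-end tests."""
    return make_fixture(seed=0)
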