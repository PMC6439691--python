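import pytest

from chipcall.panel import toy_panel


@pytest.fixture(scope="session")
def panel():
    """Default 4-gene dual-set toy panel."""
    return toy_panel(seed=11)
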