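import pytest

from psocidchip.chip_io import build_default_layout
from psocidchip.panel import load_default_panel


@pytest.fixture(scope="session")
def panel():
    return load_default_panel()


@pytest.fixture(scope="session")
def layout(panel):
    return build_default_layout(panel)
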