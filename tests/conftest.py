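import numpy as np
import pytest

from petchain.geometry import ScannerSpec, build_scanner, desk_layout


@pytest.fixture(scope="session")
def model():
    return build_scanner(ScannerSpec())


@pytest.fixture(scope="session")
def layout():
    return desk_layout()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
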