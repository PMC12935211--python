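import pytest

from woundtwin.config import default_params


@pytest.fixture(scope="session")
def params():
    """Shipped calibrated parameter set (physiology, thermo, device)."""
    return default_params()


@pytest.fixture(scope="session")
def phys(params):
    return params.physiology


@pytest.fixture(scope="session")
def thermo(params):
    return params.thermo


@pytest.fixture(scope="session")
def device_cfg(params):
    return params.device
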