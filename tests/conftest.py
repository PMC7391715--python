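import numpy as np
import pytest

from trapnoise import DeviceModel, TrapModel, nanowire_device, nanowire_trap


@pytest.fixture(scope="session")
def device() -> DeviceModel:
    """Reference 100 nm x 100 nm nanowire device (C_total = 7.1e-17 F)."""
    return nanowire_device()


@pytest.fixture(scope="session")
def trap() -> TrapModel:
    """Reference trap with symmetric rate 488 1/s and enhanced amplitude."""
    return nanowire_trap()


@pytest.fixture(scope="session")
def charge_trap() -> TrapModel:
    """Trap with the plain single-charge amplitude q* = 0.5 q."""
    return nanowire_trap(q_star_factor=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
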