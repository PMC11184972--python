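import numpy as np
import pytest

from phosdec.stimulus_design import build_stimulus_registry, build_task_registry
from phosdec.synthetic_data import make_channel_layout


@pytest.fixture(scope="session")
def registry():
    return build_stimulus_registry()


@pytest.fixture(scope="session")
def tasks(registry):
    return {t.name: t for t in build_task_registry(registry)}


@pytest.fixture(scope="session")
def layout32():
    return make_channel_layout(32)


@pytest.fixture(scope="session")
def layout8():
    return make_channel_layout(8)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
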