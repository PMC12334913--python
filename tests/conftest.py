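import numpy as np
import pytest

from vcdesign.fixtures import staircase_like_protocol, toy_3step_protocol
from vcdesign.gating import beattie_model, wang_model
from vcdesign.protocols import Protocol, Segment, common_head, with_head_and_tail


@pytest.fixture(scope="session")
def beattie():
    return beattie_model()


@pytest.fixture(scope="session")
def wang():
    return wang_model()


@pytest.fixture(scope="session")
def head():
    return common_head()


@pytest.fixture(scope="session")
def toy_protocol():
    """Head + 3-step toy body + tail: small but exercises ramps and steps."""
    return with_head_and_tail(toy_3step_protocol())


@pytest.fixture(scope="session")
def staircase():
    return staircase_like_protocol()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
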