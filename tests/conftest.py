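import numpy as np
import pytest

from soundseek.arena import ArenaGeometry


@pytest.fixture(scope="session")
def arena():
    return ArenaGeometry.default()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
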