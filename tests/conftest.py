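import numpy as np
import pytest

from rrmsim.params import EngineParams


@pytest.fixture()
def default_params() -> EngineParams:
    return EngineParams.with_overrides()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
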