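import numpy as np
import pytest

import parabead as pb


@pytest.fixture()
def toy_grid_field():
    """51-node flat unit field on [0, 10] — small enough for naive loops."""
    field = pb.init_para_field(1.0, 0.0, 10.0, 0.2, seed=0)
    assert field.grid.size == 51
    return field


@pytest.fixture()
def default_numerics():
    return pb.NumericsConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
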