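import numpy as np
import pytest

from swirlkit.kinematics import EnvConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    return EnvConfig(dt=0.1, T=50, F_max=1.0, v_max=1.0, a_max=1.0, d_t=2.0, e_t=0.5, d_cz=0.5)
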