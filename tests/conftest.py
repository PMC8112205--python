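import numpy as np
import pytest

from raftadhesion.model_core import LatticeState, ModelParams


@pytest.fixture
def params():
    return ModelParams(kappa=10.0, a=10.0, u_b=6.0, l_b=1.0, l_c=15.0, u_a=3.0, u=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_state():
    return LatticeState.flat(8, 20.0)


@pytest.fixture
def random_state(rng):
    """Small dense state exercising every energy term."""
    L = 8
    st = LatticeState.flat(L, 15.0)
    st.l += rng.uniform(-2.0, 2.0, size=(L, L))
    st.m_plus = (rng.random((L, L)) < 0.3).astype(np.uint8)
    st.m_minus = (rng.random((L, L)) < 0.3).astype(np.uint8)
    st.n_plus = (rng.random((L, L)) < 0.4).astype(np.uint8)
    return st
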