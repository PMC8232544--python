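import numpy as np
import pytest

from lgca.lattice import LatticeGeometry


@pytest.fixture
def geom_1d():
    """1D lattice geometry without rest channels (K = 2)."""
    return LatticeGeometry(dimension=1, shape=(5,), a=0)


@pytest.fixture
def geom_1d_rest():
    """1D lattice geometry with two rest channels (K = 4)."""
    return LatticeGeometry(dimension=1, shape=(5,), a=2)


@pytest.fixture
def geom_2d():
    """2D square lattice geometry without rest channels (K = 4)."""
    return LatticeGeometry(dimension=2, shape=(5, 5), a=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def tiled_1d_state(s, s_left, s_right, n_tiles, a=0, signal_pattern=None,
                   field_value=None):
    """Period-5 1D lattice: every node ≡ 2 (mod 5) carries ``s`` with left
    neighbour ``s_left`` and right neighbour ``s_right`` — giving ``n_tiles``
    independent realisations of the same (s, s_N) through the full
    synchronous update path."""
    import lgca

    L = 5 * n_tiles
    state = lgca.create_lattice(1, [L], a=a)
    occ = state.occupancy
    occ[1::5] = np.asarray(s_left, dtype=np.uint8)
    occ[2::5] = np.asarray(s, dtype=np.uint8)
    occ[3::5] = np.asarray(s_right, dtype=np.uint8)
    if signal_pattern is not None:
        sig = np.zeros(L)
        for off, v in enumerate(signal_pattern):
            sig[off::5] = v
        state.signal = sig
    if field_value is not None:
        state.field = np.full((L, 1), float(field_value))
    return state
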