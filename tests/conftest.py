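import numpy as np
import pytest

from axmorph.cpm import (
    AdhesionMatrix,
    CellRecord,
    CellType,
    LatticeState,
    ModelParams,
    PotentialField,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def params():
    return ModelParams(lambda_V=1.3, lambda_S=0.7, lambda_M=2.0, T=5.0)


@pytest.fixture
def adhesion(rng):
    A = rng.normal(0.0, 3.0, (5, 5))
    return AdhesionMatrix(A + A.T)


@pytest.fixture
def field():
    return PotentialField(slope=1.0, anterior_favourable=True)


def make_random_state(rng, n=30, n_cells=15, params=None):
    """Random owner grid with per-cell records, recounted bookkeeping."""
    if params is None:
        params = ModelParams(T=1.0)
    st = LatticeState((n, n), 2.0)
    for cid in range(1, n_cells + 1):
        st.cells[cid] = CellRecord(
            id=cid,
            type=CellType(int(rng.integers(1, 5))),
            V0=float(rng.integers(3, 30)),
            S0=float(rng.integers(5, 40)),
        )
    st.owner[:, :] = rng.integers(0, n_cells + 1, (n, n)).astype(np.int32)
    st.recount(params)
    return st


def make_single_cell_state(shape=(40, 40), anchor=(18, 18), side=5, ctype=CellType.NC,
                           V0=None, S0=None, site_size=2.0):
    st = LatticeState(shape, site_size)
    sites = np.array(
        [(anchor[0] + i, anchor[1] + j) for i in range(side) for j in range(side)]
    )
    V0 = side**2 if V0 is None else V0
    S0 = (20 + 12 * (side - 2)) if S0 is None else S0
    st.add_cell(CellRecord(id=1, type=ctype, V0=V0, S0=S0), sites)
    params = ModelParams(T=1.0)
    st.recount(params)
    return st
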