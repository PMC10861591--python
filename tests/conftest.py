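import numpy as np
import pytest

from probkd import StoichiometryMatrix, ag_network, toy_cycle_T1


@pytest.fixture(scope="session")
def t1():
    return toy_cycle_T1()


@pytest.fixture(scope="session")
def ag():
    return ag_network()


@pytest.fixture()
def full_column_rank_matrix():
    """4x3 matrix with independent columns: trivial null space."""
    entries = np.array(
        [[-1, 0, 0], [1, -1, 0], [0, 1, -1], [0, 0, 1]], dtype=np.int64
    )
    return StoichiometryMatrix(entries, ("A", "B", "C", "D"), ("r1", "r2", "r3"))
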