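import numpy as np
import pytest
from scipy import sparse

from clonegrower import ModelParams, ReadCountData


@pytest.fixture
def toy_counts() -> ReadCountData:
    """4 cells x 3 SNVs with hand-chosen counts and 2 copy-number bins."""
    A = sparse.csr_matrix(
        np.array(
            [
                [2, 0, 0],
                [1, 0, 0],
                [0, 3, 0],
                [0, 2, 1],
            ]
        )
    )
    D = sparse.csr_matrix(
        np.array(
            [
                [3, 1, 0],
                [2, 0, 0],
                [0, 4, 1],
                [1, 3, 2],
            ]
        )
    )
    R = np.array(
        [
            [10.0, 20.0],
            [12.0, 22.0],
            [30.0, 5.0],
            [28.0, 6.0],
        ]
    )
    return ReadCountData(
        cell_ids=[f"c{i}" for i in range(4)],
        snv_ids=[f"s{q}" for q in range(3)],
        A=A,
        D=D,
        R=R,
        bin_ids=["b0", "b1"],
    )


@pytest.fixture
def default_params() -> ModelParams:
    return ModelParams(seed=0)
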