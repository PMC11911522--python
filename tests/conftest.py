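import numpy as np
import pytest

from stsisal.data import ExpressionMatrix
from stsisal.simulate import make_reference, simulate_spots


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """5 genes x 4 spots with simple integer counts."""
    vals = np.array([
        [1.0, 2.0, 3.0, 4.0],
        [0.0, 0.0, 5.0, 5.0],
        [2.0, 2.0, 2.0, 2.0],
        [0.0, 1.0, 0.0, 1.0],
        [7.0, 0.0, 0.0, 3.0],
    ])
    return ExpressionMatrix(vals, [f"g{i}" for i in range(5)],
                            [f"s{j}" for j in range(4)])


@pytest.fixture(scope="session")
def small_truth():
    """A small K=3 simulation reused by several recovery tests."""
    ref = make_reference(K=3, L=400, n_markers_per_type=25, seed=11,
                         marker_fold=12.0)
    return ref, simulate_spots(ref, n_regions=3, spots_per_region=40,
                               het_rate=0.2, seed=11)
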