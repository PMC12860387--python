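import numpy as np
import pytest

from spotdecon.data_io import SpotCoordinates, SpotExpressionMatrix
from spotdecon.simulator import generate_synthetic_scrna


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_reference():
    return generate_synthetic_scrna(n_cells=120, n_genes=40, n_types=3,
                                    marker_fold=6.0, base_rate=1.0, seed=3)


@pytest.fixture
def grid_coords():
    """A 6x6 regular grid of spots, 10 px pitch."""
    xs, ys = np.meshgrid(np.arange(6) * 10.0, np.arange(6) * 10.0)
    xy = np.column_stack([xs.ravel(), ys.ravel()])
    ids = [f"s{i}" for i in range(36)]
    return SpotCoordinates(xy, ids)


@pytest.fixture
def counts_matrix(rng):
    vals = rng.integers(0, 20, size=(8, 12))
    return SpotExpressionMatrix(vals, [f"s{i}" for i in range(8)],
                                [f"g{j}" for j in range(12)])
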