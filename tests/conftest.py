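import numpy as np
import pandas as pd
import pytest

from neighborex.io import ExpressionMatrix, log_normalize
from neighborex.simulate import (
    default_image_config,
    default_ngs_config,
    simulate_image_mode,
    simulate_ngs_mode,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_expr():
    """4 genes x 5 units with hand-checkable counts."""
    counts = np.array(
        [
            [5, 0, 2, 1, 0],
            [0, 3, 0, 0, 4],
            [1, 1, 1, 1, 1],
            [0, 0, 0, 0, 0],
        ]
    )
    return ExpressionMatrix(
        genes=["g1", "g2", "g3", "g4"],
        units=["u1", "u2", "u3", "u4", "u5"],
        counts=counts,
    )


@pytest.fixture(scope="session")
def image_dataset():
    """Small image-mode dataset with planted contact genes (normalized)."""
    cfg = default_image_config(seed=0, n_cells=1200)
    cells, expr, truth = simulate_image_mode(cfg)
    return cells, log_normalize(expr), truth, cfg


@pytest.fixture(scope="session")
def ngs_dataset():
    """Small NGS-mode dataset with contact and mixing-only genes."""
    cfg = default_ngs_config(seed=0, n_spots=1200)
    expr, deconv, truth = simulate_ngs_mode(cfg)
    return log_normalize(expr), deconv, truth, cfg


def random_cells(rng, n, n_types=3, square=1.0):
    """Uniform random cell table for graph tests."""
    xy = rng.uniform(0, square, size=(n, 2))
    types = rng.choice([f"T{i + 1}" for i in range(n_types)], size=n)
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "x": xy[:, 0],
            "y": xy[:, 1],
            "cell_type": types,
        }
    )
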