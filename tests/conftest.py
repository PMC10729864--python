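import numpy as np
import pandas as pd
import pytest

from coregnet import ContrastSet


@pytest.fixture
def strong_contrast():
    """5v5 contrast, 3 genes: strong up, strong down, flat."""
    rng = np.random.default_rng(42)
    up = np.concatenate([rng.normal(0.0, 0.1, 5), rng.normal(5.0, 0.1, 5)])
    down = np.concatenate([rng.normal(5.0, 0.1, 5), rng.normal(0.0, 0.1, 5)])
    flat = np.full(10, 3.0)
    expr = pd.DataFrame(
        np.vstack([up, down, flat]), index=["up", "down", "flat"]
    )
    return ContrastSet("c1", expr, np.repeat([0, 1], 5))


def random_binary_matrix(n_rows, n_cols, density, seed):
    rng = np.random.default_rng(seed)
    return (rng.random((n_rows, n_cols)) < density).astype(np.int8)
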