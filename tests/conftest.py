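import numpy as np
import pytest

from sinum import ExpressionMatrix


@pytest.fixture
def symmetric_gem():
    """Four cells at the corners of a unit square in (gene X, gene Y) space."""
    values = np.array([[1.0, 1.0, 2.0, 2.0], [1.0, 2.0, 1.0, 2.0]])
    return ExpressionMatrix(values, ["gx", "gy"], ["c1", "c2", "c3", "c4"],
                            is_log_transformed=True)


@pytest.fixture
def random_gem():
    rng = np.random.default_rng(42)
    values = rng.random((8, 40)) * 6.0
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(8)],
        [f"c{j}" for j in range(40)],
        is_log_transformed=True,
    )


@pytest.fixture
def raw_counts_gem():
    rng = np.random.default_rng(7)
    values = rng.poisson(4.0, size=(12, 30)).astype(float)
    values[0] = 0.0  # never expressed
    values[1, :5] = 3.0
    values[1, 5:] = 0.0  # expressed in 5 cells only
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(12)],
        [f"c{j}" for j in range(30)],
        is_log_transformed=False,
    )
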