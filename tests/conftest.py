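import numpy as np
import pytest

from agreemi import ContingencyTable, build_table

BINARY = ("positive", "negative")


def binary_table(counts):
    return build_table(counts, BINARY, BINARY)


@pytest.fixture
def scenario1():
    """Worked example: clear agreement (10, 5, 5, 20)."""
    return binary_table([[10, 5], [5, 20]])


@pytest.fixture
def scenario2():
    """Worked example: clear disagreement (5, 10, 20, 5)."""
    return binary_table([[5, 10], [20, 5]])


@pytest.fixture
def scenario3():
    """Worked example: weak/inconclusive association (5, 10, 5, 20)."""
    return binary_table([[5, 10], [5, 20]])


@pytest.fixture
def cam_famcam():
    """Pilot-study table: clinician vs family delirium screens, n = 41."""
    return binary_table([[8, 1], [1, 31]])


@pytest.fixture
def independence_table():
    """Exact product-form counts: MI is exactly zero."""
    return binary_table([[10, 10], [10, 10]])


def random_count_table(rng: np.random.Generator, max_dim: int = 6) -> ContingencyTable:
    """A valid random count table with no zero row/column marginal."""
    while True:
        m = rng.integers(2, max_dim + 1)
        q = rng.integers(2, max_dim + 1)
        counts = rng.integers(0, 30, size=(m, q)).astype(float)
        if counts.sum() > 0 and np.all(counts.sum(0) > 0) and np.all(counts.sum(1) > 0):
            return ContingencyTable(counts)
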