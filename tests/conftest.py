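import numpy as np
import pandas as pd
import pytest

from nitronet import simulate

CONDITIONS = ("LN", "HN", "induced", "reduced")


@pytest.fixture
def design8():
    """Single-replicate 2-tissue x 4-condition design (8 samples)."""
    return [(t, c, 1) for t in ("leaf", "root") for c in CONDITIONS]


@pytest.fixture
def design24():
    """The study layout: 2 tissues x 4 conditions x 3 replicates."""
    return simulate.default_design()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_adjacency(n: int, rng: np.random.Generator) -> np.ndarray:
    """Symmetric random matrix in [0, 1] with unit diagonal."""
    a = rng.random((n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a


@pytest.fixture
def small_expression(rng):
    """A 6-gene x 8-sample random expression frame."""
    genes = [f"g{i}" for i in range(6)]
    samples = [f"s{i}" for i in range(8)]
    return pd.DataFrame(rng.standard_normal((6, 8)), index=genes, columns=samples)
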