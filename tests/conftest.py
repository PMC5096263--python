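import numpy as np
import pytest

import mania


@pytest.fixture
def worked_strengths() -> mania.StrengthMatrix:
    """3-node instance with strengths 0.9, 0.8, 0.5, 0.05, 0.04, 0.03.

    Scanning its six achievable non-empty networks gives normalized
    asymmetries (1.2, 0, 2/3, 0, 1.2) at densities 1/6..5/6, so the optimum
    is the symmetric 4-edge network {0↔1, 0↔2} (density tie-breaker).
    """
    s = np.zeros((3, 3))
    s[0, 1], s[1, 0] = 0.9, 0.8
    s[0, 2], s[2, 0] = 0.5, 0.05
    s[1, 2], s[2, 1] = 0.04, 0.03
    return mania.StrengthMatrix(s)


@pytest.fixture
def worked_truth() -> mania.DirectedNetwork:
    """Ground truth {0↔1, 0↔2} matching the worked strengths."""
    g = np.zeros((3, 3), dtype=int)
    g[0, 1] = g[1, 0] = g[0, 2] = g[2, 0] = 1
    return mania.DirectedNetwork(g)


def random_strengths(rng: np.random.Generator, n: int) -> mania.StrengthMatrix:
    """Random strength matrix with distinct positive off-diagonal entries."""
    v = rng.random((n, n))
    np.fill_diagonal(v, 0.0)
    return mania.StrengthMatrix(v)
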