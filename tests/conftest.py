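import math

import numpy as np
import pytest

from circamoran import (
    WeightMatrix,
    binary_grid,
    grid_von_neumann_weights,
)


@pytest.fixture(scope="session")
def w10() -> WeightMatrix:
    """Range-1 von Neumann weights on the 10x10 grid."""
    return grid_von_neumann_weights(10, 10, 1)


@pytest.fixture(scope="session")
def checkerboard10():
    return binary_grid(10, 10, "checkerboard")


# ---------------------------------------------------------------------------
# independent oracles: literal double-loop transcriptions of the defining
# formulas, kept deliberately naive and separate from the implementation
# ---------------------------------------------------------------------------

def moran_loop(values, w_dense) -> float:
    """Moran's I by explicit double loop over unit pairs."""
    values = list(map(float, values))
    n = len(values)
    xbar = sum(values) / n
    d = [x - xbar for x in values]
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += w_dense[i][j] * d[i] * d[j]
            s0 += w_dense[i][j]
    denom = sum(di * di for di in d) / n
    return (num / s0) / denom


def circ_dist_scalar(a: float, b: float) -> float:
    return math.atan2(math.sin(a - b), math.cos(a - b))


def moran_circular_loop(phases, w_dense) -> float:
    """Circular Moran's I_theta by explicit double loop."""
    phases = list(map(float, phases))
    n = len(phases)
    cbar = sum(math.cos(p) for p in phases) / n
    sbar = sum(math.sin(p) for p in phases) / n
    xbar = math.atan2(sbar, cbar)
    d = [circ_dist_scalar(p, xbar) for p in phases]
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += w_dense[i][j] * d[i] * d[j]
            s0 += w_dense[i][j]
    denom = sum(di * di for di in d) / n
    return (num / s0) / denom


def random_weight_matrix(rng: np.random.Generator, n: int) -> WeightMatrix:
    """Dense random non-negative weights with zero diagonal (asymmetric)."""
    import scipy.sparse as sp

    w = rng.random((n, n)) * (rng.random((n, n)) < 0.4)
    np.fill_diagonal(w, 0.0)
    if not w.any():
        w[0, 1] = 1.0
    return WeightMatrix(sp.csr_array(w))
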