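import numpy as np
import pytest

from kinphase.scoring import ScoreGraph


def graph_from_matrix(wmat: np.ndarray) -> ScoreGraph:
    """Dense symmetric weight matrix -> ScoreGraph (zeros = unscored)."""
    wmat = np.asarray(wmat, dtype=float)
    n = wmat.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    keep = wmat[iu, ju] != 0
    return ScoreGraph(
        n_vertices=n,
        edge_i=iu[keep],
        edge_j=ju[keep],
        weight=wmat[iu, ju][keep],
    )


@pytest.fixture
def planted_two_cliques():
    """Two 4-vertex cliques, +5 inside, -5 across: unique optimum."""
    w = np.full((8, 8), -5.0)
    for block in (range(0, 4), range(4, 8)):
        for a in block:
            for b in block:
                w[a, b] = 5.0
    np.fill_diagonal(w, 0.0)
    return graph_from_matrix(w), [[0, 1, 2, 3], [4, 5, 6, 7]]


@pytest.fixture(scope="session")
def small_cross():
    """A modest simulated tetraploid cross shared across tests."""
    from kinphase.simulate import SimulationConfig, simulate_cross

    return simulate_cross(SimulationConfig(k=4, m=120, p=60, coverage=6.0, seed=11))
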