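import numpy as np
import pytest

from pprkit.connectome import Connectome, build_laplacian
from pprkit.synthetic import seed_vector, synth_connectome


@pytest.fixture(scope="session")
def small_connectome():
    """Deterministic 20-region connected graph."""
    return synth_connectome(n_regions=20, target_sparsity=0.5, seed=42)


@pytest.fixture(scope="session")
def small_laplacian(small_connectome):
    return build_laplacian(small_connectome, kind="normalized")


@pytest.fixture(scope="session")
def brain_connectome():
    """86-region connectome-like graph at the canonical ~85% sparsity."""
    return synth_connectome(n_regions=86, target_sparsity=0.85, seed=7)


@pytest.fixture(scope="session")
def brain_laplacian(brain_connectome):
    return build_laplacian(brain_connectome, kind="normalized")


@pytest.fixture(scope="session")
def brain_x0(brain_laplacian):
    return seed_vector(brain_laplacian.labels)


@pytest.fixture()
def two_node_laplacian():
    """Unit-edge 2-node graph: H = [[1,-1],[-1,1]], eigenvalues {0, 2}."""
    conn = Connectome(np.array([[0.0, 1.0], [1.0, 0.0]]), ("a", "b"))
    return build_laplacian(conn, kind="unnormalized")


def random_connected_laplacian(rng, n, kind="normalized", density=0.3):
    """Random connected weighted graph Laplacian for property tests."""
    while True:
        W = np.zeros((n, n))
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(iu.size) < density
        W[iu[mask], ju[mask]] = rng.lognormal(0.0, 1.0, size=mask.sum())
        W += W.T
        conn = Connectome(W, tuple(f"r{i}" for i in range(n)))
        if conn.n_components() == 1:
            return build_laplacian(conn, kind=kind)
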