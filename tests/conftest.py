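import numpy as np
import pytest
import scipy.sparse as sp

from ecdcdgi import GeneGraph, ModelConfig, SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Small, fast model for unit tests (not the reference defaults)."""
    return ModelConfig(hidden_dim=8, n_layers=2, epochs=5)


@pytest.fixture
def small_graph():
    """60-gene planted-signal graph, quick to train on."""
    return generate(
        SyntheticSpec(n_nodes=60, attach_m=2, n_features=10, n_informative=4,
                      labeled_fraction=0.8, seed=3)
    )


def random_graph(rng, n=20, f=6, p_edge=0.2, labeled=0.8):
    """Erdos-Renyi-ish random GeneGraph for structural tests."""
    upper = np.triu(rng.random((n, n)) < p_edge, k=1).astype(float)
    A = upper + upper.T
    X = rng.normal(size=(n, f))
    y = np.full(n, np.nan)
    lab = rng.random(n) < labeled
    y[lab] = rng.integers(0, 2, int(lab.sum())).astype(float)
    # ensure both classes
    idx = np.flatnonzero(lab)
    if len(idx) >= 2:
        y[idx[0]], y[idx[1]] = 0.0, 1.0
    ids = [f"g{i:03d}" for i in range(n)]
    return GeneGraph(node_ids=ids, A=sp.csr_array(A), X=X, y=y)


@pytest.fixture
def make_random_graph(rng):
    def _make(**kw):
        return random_graph(rng, **kw)
    return _make
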