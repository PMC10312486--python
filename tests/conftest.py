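import numpy as np
import pytest

from cellattn import (
    ArchitectureConfig,
    SimulationConfig,
    TrainConfig,
    simulate,
    train,
)
from cellattn.containers import CountMatrix
from cellattn.model import attention_forward, init_state


def make_matrix(counts, gene_names=None, cell_ids=None, labels=None):
    counts = np.asarray(counts, dtype=float)
    c, n = counts.shape
    if gene_names is None:
        gene_names = [f"g{i}" for i in range(n)]
    if cell_ids is None:
        cell_ids = [f"c{i}" for i in range(c)]
    return CountMatrix(
        counts,
        np.array(gene_names, dtype=object),
        np.array(cell_ids, dtype=object),
        None if labels is None else np.array(labels, dtype=object),
    )


@pytest.fixture(scope="session")
def small_sim():
    """Planted-marker dataset small enough for second-scale training."""
    cfg = SimulationConfig(
        n_cells=600, n_genes=100, n_types=3, markers_per_type=8, marker_fold=8, seed=7
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_trained(small_sim):
    """(dataset, trained state, history) on the small planted fixture."""
    arch = ArchitectureConfig(n_genes=100, n_classes=3, seed=7)
    cfg = TrainConfig(epochs=15, seed=7)
    state, history = train(small_sim.matrix, arch, cfg)
    return small_sim, state, history


@pytest.fixture(scope="session")
def small_attention(small_trained):
    ds, state, _ = small_trained
    a, _ = attention_forward(ds.matrix.counts, state)
    return a


@pytest.fixture
def tiny_state():
    """Generic small state (N=8, h=4, k=2) with non-trivial parameters."""
    arch = ArchitectureConfig(n_genes=8, n_classes=3, n_blocks=2, n_branches=4, bottleneck=6, seed=5)
    state = init_state(arch)
    rng = np.random.default_rng(11)
    for k in state.params:
        state.params[k] = state.params[k] + rng.normal(0, 0.1, state.params[k].shape)
    return state
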