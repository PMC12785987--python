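import numpy as np
import pytest

from scanmf import (ExpressionMatrix, ModelConfig, PriorSet, SimulationConfig,
                    corrupt_labels, simulate)


@pytest.fixture(scope="session")
def small_sim():
    """A small, noisy simulated dataset: 150 cells, 3 types, 5 markers each."""
    cfg = SimulationConfig(n_cells=150, n_types=3, markers_per_type=5,
                           n_background_genes=30)
    return simulate(cfg, seed=11)


@pytest.fixture(scope="session")
def small_sim_labels(small_sim):
    return corrupt_labels(small_sim.true_labels, retain_fraction=0.2, seed=12)


@pytest.fixture
def fast_config():
    return ModelConfig(max_iter=30)


@pytest.fixture
def toy_matrix():
    """4 genes x 3 cells with one mitochondrial gene."""
    values = np.array([
        [5.0, 0.0, 1.0],
        [0.0, 2.0, 1.0],
        [3.0, 1.0, 0.0],
        [1.0, 1.0, 1.0],  # MT-CO1
    ])
    return ExpressionMatrix(values, ["GENE_A", "GENE_B", "GENE_C", "MT-CO1"],
                            ["c1", "c2", "c3"])


def random_priors(rng, m, n, p):
    """Unstructured binary constraint matrices for optimizer stress tests."""
    M = (rng.random((m, p)) < 0.5).astype(float)
    P = (rng.random((n, p)) < 0.5).astype(float)
    return PriorSet(M, P, [f"t{k}" for k in range(p)],
                    marker_gene_count=m, labeled_cell_count=0,
                    labeled_mask=np.zeros(n, dtype=bool))
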