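import numpy as np
import pytest

import scnormlm as sc


@pytest.fixture
def toy_counts() -> sc.CountMatrix:
    """4 genes x 4 cells with one low-depth cell and one fragile gene."""
    counts = np.array(
        [
            [3, 3, 3, 1],
            [2, 2, 2, 0],
            [2, 2, 2, 0],
            [0, 0, 2, 1],
        ]
    )
    return sc.CountMatrix(counts, ["g1", "g2", "g3", "g4"], ["c1", "c2", "c3", "c4"])


@pytest.fixture(scope="session")
def null_dataset() -> sc.SyntheticDataset:
    """Small co-expression-free dataset reused across tests."""
    d = sc.parametric_distributions(n_genes=120)
    cfg = sc.SimulationConfig(n_cells=400, n_genes=120, sigma=0.5, seed=11)
    return sc.simulate_null(d, cfg)


@pytest.fixture(scope="session")
def normalized_null(null_dataset) -> sc.NormalizedExpression:
    m, _ = sc.qc_filter(null_dataset.counts)
    return sc.normalize_counts(m)
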