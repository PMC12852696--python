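import warnings

import numpy as np
import pytest

from neurotransit.matrix import CountMatrix
from neurotransit.simulate import CountsSimParams, simulate_counts


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Silence the deliberate small-sample / missing-gene warnings in bulk runs."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def small_sim():
    """Default-parameter synthetic count matrix with contaminants (seeded)."""
    cm, truth = simulate_counts(
        CountsSimParams(n_cells=800, n_genes=300, contaminant_frac=0.2), seed=11
    )
    return cm, truth


@pytest.fixture
def tiny_matrix():
    """Hand-sized 4 genes x 3 cells matrix with one mito gene."""
    counts = np.array(
        [
            [3, 0, 1],  # MT-1
            [7, 2, 0],
            [0, 5, 4],
            [0, 0, 2],
        ]
    )
    return CountMatrix(
        counts=counts,
        gene_ids=np.array(["MT-1", "GeneA", "GeneB", "GeneC"], dtype=object),
        cell_ids=np.array(["c1", "c2", "c3"], dtype=object),
    )
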