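import logging

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from adaptiveqc import (
    CountMatrix,
    MarkerDatabase,
    compute_cell_metrics,
    generate_atlas,
    preset_fixtures,
    run_adaptive_qc,
    tag_gene_categories,
)

logging.getLogger("adaptiveqc").setLevel(logging.ERROR)


def make_matrix(dense, genes=None, barcodes=None) -> CountMatrix:
    dense = np.asarray(dense)
    n_cells, n_genes = dense.shape
    genes = genes or [f"G{j}" for j in range(n_genes)]
    barcodes = barcodes or [f"bc{i}" for i in range(n_cells)]
    return CountMatrix(sp.csr_matrix(dense), barcodes, genes)


@pytest.fixture(scope="session")
def marker_db() -> MarkerDatabase:
    return MarkerDatabase.load_builtin()


@pytest.fixture(scope="session")
def heart_run():
    """heart_like atlas plus a full adaptive QC run (shared; expensive)."""
    matrix, truth = generate_atlas(preset_fixtures("heart_like", seed=0))
    result = run_adaptive_qc(matrix)
    return matrix, truth, result


@pytest.fixture(scope="session")
def small_atlas():
    """Small 3-cluster atlas for cheap end-to-end tests."""
    from adaptiveqc import ClusterSpec, SyntheticSpec

    spec = SyntheticSpec(
        clusters=[
            ClusterSpec("a", 120, 800, 4.0, 15.0),
            ClusterSpec("b", 120, 1200, 6.0, 12.0),
            ClusterSpec("c", 120, 400, 3.0, 20.0),
        ],
        n_genes=1500,
        random_seed=7,
    )
    return generate_atlas(spec)


@pytest.fixture()
def random_metrics():
    """Random but reproducible per-cell QC metric table with cluster labels."""
    rng = np.random.default_rng(42)
    n = 400
    labels = rng.integers(0, 5, n)
    metrics = pd.DataFrame(
        {
            "n_counts": rng.lognormal(8, 0.6, n),
            "n_genes": rng.integers(80, 4000, n).astype(float),
            "percent_mito": rng.uniform(0, 40, n),
            "percent_ribo": rng.uniform(0, 50, n),
        },
        index=[f"bc{i}" for i in range(n)],
    )
    return metrics, labels
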