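import numpy as np
import pytest
import scipy.sparse as sp

from limbatlas.io import CountMatrix, GeneClassMap
from limbatlas.qc_norm import QCThresholds, compute_qc_metrics, filter_cells, lognormalize
from limbatlas.synthetic import preset, simulate_atlas, with_seed


@pytest.fixture
def toy_counts():
    """5 genes x 4 cells with hand-checkable counts."""
    X = np.array(
        [
            [3, 0, 1, 0],
            [0, 5, 2, 0],
            [1, 1, 0, 4],
            [0, 0, 0, 0],
            [2, 3, 1, 1],
        ]
    )
    return CountMatrix(
        sp.csr_matrix(X),
        [f"G{i}" for i in range(5)],
        [f"name{i}" for i in range(5)],
        [f"BC{i}" for i in range(4)],
    )


@pytest.fixture
def gene_classes():
    return GeneClassMap({"G0": "mitochondrial", "G1": "ribosomal"})


@pytest.fixture(scope="session")
def qc_outlier_atlas():
    return simulate_atlas(preset("qc_outliers"))


@pytest.fixture(scope="session")
def three_pop_atlas():
    return simulate_atlas(preset("three_pops"))


def filtered_normalized(cm, classes):
    """Shared helper: QC-filter then log-normalize a simulated atlas."""
    qc = compute_qc_metrics(cm, classes)
    _, qct = filter_cells(qc, QCThresholds())
    mask = qct["keep"].to_numpy()
    cmf = cm.subset_cells(mask)
    return cmf, lognormalize(cmf), mask


@pytest.fixture(scope="session")
def module_atlas_prepared():
    cm, truth = simulate_atlas(preset("planted_modules"))
    cmf, nm, mask = filtered_normalized(cm, truth.gene_classes)
    return cm, truth, cmf, nm, mask
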