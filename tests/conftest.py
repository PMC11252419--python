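import numpy as np
import pytest

from semiprofile import (
    SyntheticCohortSpec,
    generate_cohort,
    generate_gene_sets,
)
from semiprofile.pipeline import process_representatives, synthetic_qc_config


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cohort():
    """Six samples, 40 genes, 3 cell types — enough structure for the
    bulk/selection/evaluation unit tests without heavy compute."""
    spec = SyntheticCohortSpec(n_samples=6, n_genes=40, n_cell_types=3,
                               cells_per_sample=80, seed=7)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def gene_sets(small_cohort):
    return generate_gene_sets(4, small_cohort.gene_ids, seed=3)


@pytest.fixture(scope="session")
def rep_cells(small_cohort, gene_sets):
    """Augmented cells of the first sample, shared across model tests."""
    return process_representatives(
        small_cohort, [small_cohort.sample_ids[0]], gene_sets,
        qc=synthetic_qc_config(knn_k=10))[small_cohort.sample_ids[0]]
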