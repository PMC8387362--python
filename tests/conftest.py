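import numpy as np
import pytest

from hrdscan.genes import placeholder_gene_lists, synthetic_gene_intervals
from hrdscan.genome import hg19_autosomes
from hrdscan.signatures import calibrate_sig3_threshold, synthetic_signature_matrix
from hrdscan.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def layout():
    return hg19_autosomes()


@pytest.fixture(scope="session")
def matrix():
    return synthetic_signature_matrix()


@pytest.fixture(scope="session")
def calibration(matrix):
    """Signature-3 threshold calibrated at 5% FPR (shared across tests)."""
    return calibrate_sig3_threshold(matrix, n_sims=1000, fpr=0.05, seed=101)


@pytest.fixture(scope="session")
def gene_lists():
    return placeholder_gene_lists()


@pytest.fixture(scope="session")
def gene_intervals(gene_lists, layout):
    return synthetic_gene_intervals(gene_lists, layout)


@pytest.fixture(scope="session")
def small_cohort():
    """A 10-patient cohort with two spiked causal patients."""
    return simulate_cohort(SimulationConfig(n_patients=10, causal_fraction=0.2,
                                            seed=424242))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210825)
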