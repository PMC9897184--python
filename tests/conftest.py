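import numpy as np
import pytest

from lactopop import popgen, simdata


@pytest.fixture(scope="session")
def cohort():
    """One default 41-strain, 5-clade cohort, shared across tests."""
    spec = simdata.default_cohort_spec(seed=3)
    table, genes, truth = simdata.simulate_structured_cohort(spec)
    return spec, table, genes, truth


@pytest.fixture(scope="session")
def cohort_divergence(cohort):
    spec, table, _, _ = cohort
    return popgen.pairwise_divergence_matrix(table, spec.genome_length)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
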