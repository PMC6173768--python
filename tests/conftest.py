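import numpy as np
import pytest

from cnaload import make_genome_layout, run_pipeline, simulate_cohort
from cnaload.synthetic import CohortConfig


@pytest.fixture(scope="session")
def toy_layout():
    """Two small chromosomes (10 and 8 bins) for hand-computable examples."""
    return make_genome_layout(bins_per_chromosome=[10, 8])


@pytest.fixture(scope="session")
def cohort300():
    """Default-archetype cohort at the standard study mixture."""
    return simulate_cohort(CohortConfig(n_samples=300, seed=17))


@pytest.fixture(scope="session")
def pipeline300(cohort300):
    return run_pipeline(cohort300, n_perm=120, reps=150, seed=17)


@pytest.fixture(scope="session")
def truth300(cohort300):
    return cohort300.clinical.set_index("sample_id")["true_cluster"]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
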