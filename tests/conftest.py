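import numpy as np
import pytest

from moprog.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """Desk-scale cohort: same structure as the default, smaller sizes."""
    return CohortConfig(
        n_samples=150,
        n_meth_probes=800,
        n_genes=600,
        n_mirnas=100,
        mutation_burden_means=(120.0, 40.0, 70.0),
        seed=1,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
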