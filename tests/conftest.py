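import numpy as np
import pytest

from radstab.synthetic import (CohortConfig, generate_feature_cohort,
                               generate_phantom_volumes)


@pytest.fixture(scope="session")
def feature_cohort():
    """Default-size simulated feature cohort, shared across tests."""
    return generate_feature_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def phantom_cohort():
    """Six small brain phantoms in two acquisition batches."""
    cfg = CohortConfig(
        n_patients=6, batch_size_distribution=(3, 3),
        n_batches_per_sequence=2, age_mean_by_batch=(58.0, 64.0),
        shared_batch_threshold=100, seed=5,
    )
    return cfg, generate_phantom_volumes(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
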