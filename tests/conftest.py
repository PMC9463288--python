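import numpy as np
import pytest

from endoeval.synth import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def toy_cohort():
    """Four participants, one exercise — fast shared input for unit tests."""
    cfg = CohortConfig(
        seed=7, n_participants=4, n_excluded=0, group_split=(2, 2), exercises=1
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def toy_tables(toy_cohort):
    from endoeval.table import build_feature_tables, impute_group_means

    _, recs = toy_cohort
    tables = build_feature_tables(recs)
    return {ex: impute_group_means(t) for ex, t in tables.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
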