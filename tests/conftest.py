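import numpy as np
import pytest

from cortisurv.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A scaled cohort (few genes, short promoters) shared across tests."""
    cfg = CohortConfig(seed=11, n_genes=300, n_up=20, n_down=10, promoter_len=600)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-calibration cohort without the genomic stages (fast)."""
    cfg = CohortConfig(seed=42, n_genes=0, n_up=0, n_down=0)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
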