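import numpy as np
import pytest

from nodulediag.cohort import (
    fit_default_cutoffs,
    nodule_cohort_config,
    sample_cohort,
)

SEED = 11


@pytest.fixture(scope="session")
def nodule_config():
    return nodule_cohort_config(seed=SEED)


@pytest.fixture(scope="session")
def nodule_cohort(nodule_config):
    return sample_cohort(nodule_config)


@pytest.fixture(scope="session")
def default_cutoffs(nodule_config):
    return fit_default_cutoffs(nodule_config.moments)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
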