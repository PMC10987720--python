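import numpy as np
import pytest

import wmtransfer as wt


@pytest.fixture(scope="session")
def lexicon():
    return wt.default_lexicon(seed=0)


@pytest.fixture(scope="session")
def verbal_forms(lexicon):
    """(list_a, list_b, inclusion, exclusion) for version 1, seed 0."""
    return wt.build_verbal_form(lexicon, version=1, seed=0)


@pytest.fixture(scope="session")
def spatial_forms():
    """(study_set, global_form, local_form) for version 1, seed 0."""
    return wt.build_spatial_form(wt.default_image_pool(1), version=1, seed=0)


@pytest.fixture(scope="session")
def default_run():
    """One full simulated trial at the default configuration."""
    cfg = wt.StudyConfig()
    cohort = wt.generate_cohort(cfg, seed=1)
    return wt.simulate_trial_run(cohort, cfg, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
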