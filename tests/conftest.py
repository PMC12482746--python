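import dataclasses

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cakival.synthetic_cohort import default_config, generate_cohort


@pytest.fixture(scope="session")
def default_cfg():
    return default_config()


@pytest.fixture(scope="session")
def default_cohort(default_cfg):
    """Default study-sized cohort (n=1684, seed 0) plus its truth table."""
    cfg = dataclasses.replace(default_cfg, seed=0)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def big_cohort(default_cfg):
    """Large cohort for marginal/prevalence recovery checks."""
    cfg = dataclasses.replace(default_cfg, n_patients=50_000, seed=11)
    return generate_cohort(cfg)
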