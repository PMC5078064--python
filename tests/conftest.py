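import numpy as np
import pytest
from hypothesis import settings

from nkp44var.synthetic import default_config, generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_like_cohort():
    """Synthetic cohort with the study-like 24/12/60 group structure."""
    return generate_cohort(default_config(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
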