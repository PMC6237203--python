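import numpy as np
import pytest
from hypothesis import settings

from histofusion.synthetic import SyntheticCohortConfig, generate_cohort

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-patient cohort shared by read-only tests."""
    return generate_cohort(SyntheticCohortConfig(n_patients=20, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_tissue_patch(edge=64, tissue_cols=None, value=(200, 120, 180)):
    """Synthetic patch with the left ``tissue_cols`` columns tissue-colored
    and the rest white background (known tissue fraction)."""
    img = np.full((edge, edge, 3), 255, dtype=np.uint8)
    if tissue_cols:
        img[:, :tissue_cols] = value
    return img
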