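import numpy as np
import pytest

from strata_ifc.synthcohort import CohortSpec, TimeSeriesSpec, generate_clinical


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size synthetic cohort at the default study conditions (seeded)."""
    return generate_clinical(CohortSpec(rng_seed=20))


@pytest.fixture(scope="session")
def small_ts_spec():
    """A reduced imaging spec for fast tests: 8x8x6 grid, 60 volumes."""
    return TimeSeriesSpec(grid_shape=(8, 8, 6), n_volumes=60, rng_seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
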