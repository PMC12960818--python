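import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import icubench as ib

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def build_cohort(values, native=None, stay_ids=None):
    """Construct a cohort from a (n_stays, n_hours, 4) nested list/array."""
    values = np.asarray(values, dtype=float)
    if native is None:
        native = np.isnan(values)
    if stay_ids is None:
        stay_ids = np.arange(values.shape[0])
    return ib.Cohort(values, np.asarray(native, dtype=bool), np.asarray(stay_ids))


@pytest.fixture(scope="session")
def synthetic_small():
    """Fully observed 60-stay default synthetic cohort."""
    return ib.generate_cohort(n_stays=60, seed=0)


@pytest.fixture(scope="session")
def observed_small(synthetic_small):
    """Same cohort with native missingness overlaid."""
    return ib.overlay_native_missingness(synthetic_small, seed=1)


@pytest.fixture(scope="session")
def standardized_small(synthetic_small):
    params = ib.fit_standardization(synthetic_small)
    return ib.standardize(synthetic_small, params)
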