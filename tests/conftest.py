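import numpy as np
import pytest

from proxsurv.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Fast cohort for unit tests: 120 patients, 40 features."""
    cfg = CohortConfig(
        n_patients=120,
        n_features=40,
        n_informative=14,
        feature_shift=2.0,
        group_hazard_ratios=(1.0, 3.0),
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
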