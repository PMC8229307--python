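import numpy as np
import pandas as pd
import pytest

from saltscape.synthetic import RegionSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_spec():
    return RegionSpec(n_participants=300, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return simulate_cohort(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def participant_fixture():
    """Hand-built 5-row participant table with known covariate codings."""
    return pd.DataFrame(
        {
            "id": ["a", "b", "c", "d", "e"],
            "x": [100.0, 200.0, 300.0, 400.0, 500.0],
            "y": [100.0, 200.0, 300.0, 400.0, 500.0],
            "year": [2000, 2005, 2010, 2015, 2018],
            "age": [25.0, 35.0, 45.0, 55.0, 65.0],
            "sex": ["female", "male", "female", "male", "female"],
            "civil_status": [
                "married_cohabiting", "other", "other",
                "married_cohabiting", "married_cohabiting",
            ],
            "occupation": ["low", "medium", "high", "not_working", "low"],
            "education": ["primary", "secondary", "tertiary", "primary", "secondary"],
            "nationality": ["swiss", "other", "swiss", "swiss", "other"],
            "ffq_na": [2.0, 3.0, 4.0, 5.0, 6.0],
            "k_intake": [2.0, 2.5, 3.0, 3.5, 4.0],
            "energy": [1500.0, 2000.0, 2500.0, 3000.0, 3500.0],
            "zone_id": ["z0_0", "z0_0", "z0_0", "z0_1", "z1_1"],
        }
    )
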