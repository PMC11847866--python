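import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nssinet.cohort import CohortTable
from nssinet.synthetic import calibrate_copula, default_paper_config, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def calibrated_config():
    """Study-default synthetic config with the copula solved once."""
    return calibrate_copula(default_paper_config())


@pytest.fixture(scope="session")
def cohort_112(calibrated_config):
    """A 112-participant synthetic cohort at the study conditions."""
    import dataclasses

    cfg = dataclasses.replace(calibrated_config, n=112, seed=7)
    cohort, _ = generate_cohort(cfg)
    return cohort


@pytest.fixture()
def tiny_cohort():
    """Three hand-written records, one missing income cell."""
    df = pd.DataFrame(
        {
            "participant_id": ["a", "b", "c"],
            "age": [14.0, 15.0, np.nan],
            "gender": ["female", "male", "female"],
            "father_edu": ["primary", "secondary", "college_university"],
            "mother_edu": ["primary", "primary", "secondary"],
            "income": ["lt_100k", np.nan, "100_250k"],
            "quarrel": ["never", "monthly_1_2", "divorce"],
            "depression_band": ["severe", "no", "moderate"],
            "anxiety_band": ["severe", np.nan, "mild"],
            "self_concept": ["low", "normal", "low"],
            "suicide_high": ["high", "non_high", "non_high"],
        }
    )
    return CohortTable(df)
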