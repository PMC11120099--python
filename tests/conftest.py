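"""Shared fixtures: deterministic hypothesis profile and reference cohorts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    database=None,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_lus_cohort() -> pd.DataFrame:
    """The 84-patient cohort reproducing the published ultrasound
    cross-counts exactly (see vapscore.reference)."""
    from vapscore.reference import reference_lus_cohort

    return reference_lus_cohort()


@pytest.fixture(scope="session")
def default_cohort_500():
    """One default-config synthetic cohort, scored, reused across tests."""
    from vapscore import DEFAULT_RULES, generate_frame, score_frame

    df = generate_frame(n=500, seed=20240514)
    return score_frame(df, rules=list(DEFAULT_RULES))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
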