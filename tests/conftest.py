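import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from somnentropy import (
    CohortSpec,
    EpochScheme,
    STRONG_SEPARATION_PARAMS,
    generate_cohort,
)
from somnentropy.staging import compute_feature_table

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cohort16():
    """The default 16-subject, 6-h synthetic cohort."""
    return generate_cohort(CohortSpec(n_subjects=16, seed=7))


def _table(cohort, window_len):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return compute_feature_table(cohort, EpochScheme(window_len=window_len))


@pytest.fixture(scope="session")
def table300_default(default_cohort16):
    return _table(default_cohort16, 300)


@pytest.fixture(scope="session")
def table270_default(default_cohort16):
    return _table(default_cohort16, 270)


@pytest.fixture(scope="session")
def strong_cohort():
    """Smaller cohort with exaggerated stage contrasts for classifier checks."""
    return generate_cohort(
        CohortSpec(
            n_subjects=8,
            night_duration=3 * 3600.0,
            seed=5,
            stage_params=dict(STRONG_SEPARATION_PARAMS),
        )
    )


@pytest.fixture(scope="session")
def strong_table300(strong_cohort):
    return _table(strong_cohort, 300)
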