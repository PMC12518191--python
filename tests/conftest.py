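"""Shared fixtures: synthetic cohorts at the sizes the tests need."""

from dataclasses import replace

import pytest
from hypothesis import HealthCheck, settings

from thyrostp.cohort import (
    ResidualModel,
    Schedule,
    default_population,
    generate_cohort,
)
from thyrostp.nlme import FitConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_cohort():
    """73-patient cohort with the clinical sampling design (364 records)."""
    return generate_cohort(default_population(), 73, seed=11)


@pytest.fixture(scope="session")
def degenerate_population():
    """No inter-individual variability, no residual noise: every patient
    lies exactly on the typical curve."""
    pop = default_population()
    return replace(
        pop,
        iiv_cv=(0.0, 0.0, 0.0, 0.0),
        residual_model=ResidualModel("combined", 0.0, 0.0),
        schedule=Schedule(common_times_h=(2.0, 6.0, 24.0, 48.0, 120.0)),
    )


@pytest.fixture(scope="session")
def degenerate_cohort(degenerate_population):
    return generate_cohort(degenerate_population, 6, seed=5)


@pytest.fixture(scope="session")
def fast_fit_config():
    """Reduced multi-start budget for small test cohorts."""
    return FitConfig(seed=42, n_starts=200, n_refine=3)
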