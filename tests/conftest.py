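import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gaitsym import CohortConfig, simulate_patterns

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def symmetric_cohort():
    """Small zero-asymmetry cohort, preprocessed to patterns."""
    cfg = CohortConfig(n_subjects=6, trials_per_side=4, seed=11)
    dataset, truth = simulate_patterns(cfg)
    return dataset, truth


@pytest.fixture(scope="session")
def asymmetric_cohort():
    """Small cohort with a large force asymmetry and tiny trial noise: separable."""
    quiet = {k: 0.01 for k in ("fz1", "tz1", "fz2", "tz2", "fz3", "tz3")}
    cfg = CohortConfig(
        n_subjects=6,
        trials_per_side=4,
        seed=12,
        asymmetry={"fz1": 0.3, "fz2": 0.3, "fz3": 0.3},
        between_subject_cv=dict(quiet),
        within_trial_cv=dict(quiet),
        noise_n=0.5,
    )
    dataset, truth = simulate_patterns(cfg)
    return dataset, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
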