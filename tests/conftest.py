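import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_session():
    """One 3-subject, 2-throws-per-condition synthetic study (fast, reused)."""
    from throwsense.synthetic_data import SimulationConfig, simulate_study

    cfg = SimulationConfig(n_subjects=3, throws_per_condition=(2, 2), seed=11)
    sessions, truth = simulate_study(cfg)
    return cfg, sessions, truth


@pytest.fixture(scope="session")
def small_feature_matrix(small_session):
    """Labeled feature matrix (2 s and 3 s windows) of the small study."""
    from throwsense.pipeline import featurize_study

    _, sessions, _ = small_session
    return featurize_study(sessions, window_sizes_s=(2.0, 3.0))


@pytest.fixture(scope="session")
def default_session():
    """One subject simulated under the full default study conditions."""
    from throwsense.synthetic_data import SimulationConfig, simulate_session

    cfg = SimulationConfig(seed=5)
    return cfg, simulate_session(cfg, "S01", np.random.default_rng(5))
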