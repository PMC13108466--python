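import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pairedeval.synthetic_cohort import SimulationConfig, simulate_cohort

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_cohort():
    """Two-clinic cohort with three raters of graded noise."""
    cfg = SimulationConfig(
        n_pairs_per_clinic={"A": 60, "B": 40},
        n_raters=3,
        d=1.0,
        sigma_r=[0.5, 1.0, 2.0],
        sigma_m=0.8,
        years_experience=[3.0, 12.0, 25.0],
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
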