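import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

SEED = 20250925


@pytest.fixture(scope="session")
def seed() -> int:
    return SEED


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def noise_dataset():
    """1000 pure-noise series on the dense 48 h @ 2 h design."""
    from circabench import SimulationConfig, synthesize_dataset

    cfg = SimulationConfig(
        duration_h=48.0, interval_h=2.0, n_series=1000,
        frac_rhythmic=0.0, noise_sd=1.0, seed=SEED,
    )
    return synthesize_dataset(cfg)


@pytest.fixture(scope="session")
def rhythmic_dataset():
    """200 all-rhythmic series at amplitude/noise = 2, period 24 h."""
    from circabench import SimulationConfig, synthesize_dataset

    cfg = SimulationConfig(
        duration_h=48.0, interval_h=2.0, n_series=200, frac_rhythmic=1.0,
        amp_min=2.0, amp_max=2.0, period_min_h=24.0, period_max_h=24.0,
        noise_sd=1.0, seed=SEED + 1,
    )
    return synthesize_dataset(cfg)
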