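import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from capstrat.simconfig import SimulationConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def small_config(seed: int = 1) -> SimulationConfig:
    """The shipped defaults, shrunk to a 600 kb genome for fast tests."""
    cfg = SimulationConfig.default()
    cfg.genome.chromosomes = {"chr1": 300_000, "chr2": 300_000}
    for model in cfg.subregions.values():
        model.n_targets = max(5, model.n_targets // 40)
    cfg.seed = seed
    return cfg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_dataset():
    from capstrat.simulate import simulate_dataset

    return simulate_dataset(small_config(seed=1))
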