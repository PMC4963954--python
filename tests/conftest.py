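import pytest
from hypothesis import HealthCheck, settings

from epigsc import SimulationConfig, simulate

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def small_config(seed: int = 7, **overrides) -> SimulationConfig:
    """A scaled-down simulation (60 gene slots, one 1.08-Mb chromosome) for
    fast unit tests; recovery-grade runs use the full defaults."""
    base = dict(
        seed=seed,
        genome_length=1_080_000,
        n_genes=60,
        n_enhancers_per_class=10,
        signal_depth=200_000,
        n_te_per_family=5,
        n_dmrs=4,
        n_bivalent={"fgsc": 6, "esc": 12},
        n_repressed={"fgsc": 8, "esc": 6},
        n_silent={"fgsc": 6, "esc": 5},
        n_body_only_genes=8,
        n_knockdown_responsive=15,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    return simulate(small_config())


@pytest.fixture(scope="session")
def small_sim_config():
    return small_config()
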