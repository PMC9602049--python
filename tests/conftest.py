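import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from beepirna import pipeline
from beepirna.simulate import SimulationConfig, simulate_study

settings.register_profile(
    "default", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("default")


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    """A fast study: 60 loci, 4k reads/replicate, small genome."""
    base = dict(
        seed=seed,
        genome_length=60_000,
        n_pirna_loci=60,
        n_ncrna_loci={"rRNA": 5, "tRNA": 5, "snRNA": 3, "snoRNA": 3, "scRNA": 2},
        n_mirna=20,
        n_transcripts=80,
        mean_depth=4_000,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    return simulate_study(small_config(), tmp_path_factory.mktemp("small_study"))


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    return pipeline.run_study(small_config(), tmp_path_factory.mktemp("small_run"))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """The reference study conditions: 3x3 design, 1e5 reads/replicate,
    500 piRNA loci, 10% DE at |log2FC| = 2."""
    return pipeline.run_study(SimulationConfig(seed=1), tmp_path_factory.mktemp("default_run"))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
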