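import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from metachrom import coverage as cov
from metachrom import synthetic_data as sim
from metachrom.annotations import GeneModel

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def two_exon_plus() -> GeneModel:
    return GeneModel("gA", "chr1", "+", ((100, 200), (300, 400)))


@pytest.fixture
def two_exon_minus() -> GeneModel:
    return GeneModel("gB", "chr1", "-", ((100, 200), (300, 400)))


@pytest.fixture
def constant_track() -> cov.CoverageTrack:
    """A 2-kb chromosome uniformly covered at 1.0 RPM."""
    return cov.CoverageTrack({"chr1": np.ones(2000)}, library_size=1000, normalized=True)


@pytest.fixture(scope="session")
def small_truth() -> sim.SimulationTruth:
    """A small default-geometry simulation shared by read-only tests."""
    return sim.simulate_genome(sim.SimulationConfig(seed=42, n_genes=60))
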