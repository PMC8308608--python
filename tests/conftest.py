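import pytest
from hypothesis import settings

from diplopop import SimulationConfig, simulate_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from diplopop.model import AlignedMarkerSet, PopulationMap


@pytest.fixture(scope="session")
def study_dataset():
    """Synthetic dataset at the study's scale: 14 populations in clusters
    of 3+3+3+5, 20 diploids each, markers of 425/239 positions with 30/33
    ascertained SNPs."""
    return simulate_dataset(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def small_dataset():
    """Small 2-cluster dataset for fast pipeline-level tests."""
    cfg = SimulationConfig(
        pops_per_cluster=(2, 2),
        n_per_pop=8,
        L_per_marker=(80, 60),
        n_snps_per_marker=(8, 6),
        seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def toy_marker():
    return AlignedMarkerSet(
        "toy",
        ["s1", "s2", "s3", "s4"],
        ["ACGTA", "ACGTA", "ARGTA", "ACGTG"],
    )


@pytest.fixture
def toy_popmap():
    return PopulationMap(
        {"s1": "north", "s2": "north", "s3": "south", "s4": "south"},
        {"north": "west", "south": "east"},
    )
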