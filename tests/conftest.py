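import pytest

from indelmark import ReferenceGenome
from indelmark.simulate import SimulationConfig, plant_indels, simulate_reference


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=42)


@pytest.fixture(scope="session")
def planted(sim_config):
    """Two simulated parents with 100 A-only, 50 B-only, 25 shared InDels."""
    genome = simulate_reference(sim_config)
    return plant_indels(genome, sim_config)


@pytest.fixture()
def tiny_genome():
    return ReferenceGenome(
        sequences={
            "chrA": "ACGTACGTACCAAATGCGTACGATCGATCGTAGCTAGCTAACGTACGTAA",
            "chrB": "TTTTGGGGCCCCAAAATTTTGGGGCCCCAA",
        }
    )
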