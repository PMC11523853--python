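import numpy as np
import pytest

from mucosim.core_types import (
    AgentPopulation,
    DomainSpec,
    KineticEntry,
    ScenarioConfig,
    SpeciesSpec,
    SubstrateSpec,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_domain():
    return DomainSpec(width=50.0, height=50.0, grid_dx=10.0, biofilm_height_cap=30.0)


@pytest.fixture
def one_species_config():
    """Minimal single-species scenario on a small domain."""
    return ScenarioConfig(
        domain=DomainSpec(width=50.0, height=100.0, grid_dx=10.0, biofilm_height_cap=30.0),
        substrates=[SubstrateSpec(id="S1")],
        species=[SpeciesSpec(id="A", kinetics=[KineticEntry("S1", mu_max=0.3)])],
        initial_abundance={"A": 1.0},
        seed_count=10,
        max_time_h=10.0,
        rng_seed=7,
    )


def make_population(species_ids, rows):
    """rows: list of (species_idx, mass, x, y) tuples, all frozen."""
    pop = AgentPopulation(species_ids)
    if rows:
        arr = np.array(rows, dtype=float)
        pop.add(
            species=arr[:, 0].astype(int),
            mass=arr[:, 1],
            x=arr[:, 2],
            y=arr[:, 3],
            frozen=True,
        )
    return pop
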