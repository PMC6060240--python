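import pytest

from microdiv.simulate import SimParams, simulate_population


@pytest.fixture(scope="session")
def small_pop():
    """A small recombining population shared across read-only tests."""
    params = SimParams(seed=11, core_length=60_000, theta_site=2e-3, rho_rel=0.1,
                       mean_tract=2_000, n_core_genes=40, n_accessory_families=30,
                       island_hotspots=2, plasmid_rate=0.5)
    genomes, truth, matrix, blocks = simulate_population(params)
    return params, genomes, truth, matrix, blocks


@pytest.fixture(scope="session")
def clonal_pop():
    """A purely clonal population (no recombination) for tree/CF tests."""
    params = SimParams(seed=23, core_length=80_000, theta_site=3e-3, rho_rel=0.0,
                       n_core_genes=40, n_accessory_families=20)
    genomes, truth, matrix, blocks = simulate_population(params)
    return params, genomes, truth, matrix, blocks
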