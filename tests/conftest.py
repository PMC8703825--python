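import pytest

from tbpkit.simulate import simulate_clones, simulate_pools


@pytest.fixture(scope="session")
def four_species_pools():
    """Well-diverged four-species allele pools (fixed seed)."""
    return simulate_pools(4, divergence=8.0, seed=1)


@pytest.fixture(scope="session")
def reciprocal_cohort(four_species_pools):
    """The reference study cohort: 4 species x 12 clones plus 12 hybrids of
    one cross, 6 per reciprocal direction, no CE noise."""
    hybrids = [("sp1", "sp3", "sp1", 6), ("sp1", "sp3", "sp3", 6)]
    return simulate_clones(four_species_pools, 12, hybrids=hybrids,
                           het_prob=0.1, seed=2)
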